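"""Matrix cleaning applied to each profile before any screening.

The rules, applied per matrix (TF expression, gene expression, methylation)
independently:

1. drop features whose value is exactly 0 in every sample;
2. replace any remaining 0 with the smallest nonzero value of the whole
   matrix (the literal global minimum would be 0 and change nothing);
3. log2-transform every value;
4. where several probes map to one gene symbol, average them into a single
   row per symbol.

log2 is strictly monotone, so the rank-based methylation stratification
downstream is unaffected by whether the methylation matrix is transformed;
by default it is, like the expression matrices (``log2_meth=False`` in
:func:`preprocess_pipeline` opts out).
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .errors import DegenerateInputError, EmptyMatrixError

__all__ = [
    "drop_all_zero_rows",
    "impute_zeros_min",
    "log2_transform",
    "collapse_probes",
    "preprocess_pipeline",
]


def drop_all_zero_rows(m: OmicsMatrix) -> OmicsMatrix:
    """Remove features that are exactly 0 in all samples, preserving order."""
    vals = m.values
    keep = ~(vals == 0).all(axis=1)
    if not keep.any():
        raise EmptyMatrixError("every feature is zero in all samples")
    return m.with_values(vals.loc[keep])


def impute_zeros_min(m: OmicsMatrix) -> OmicsMatrix:
    """Replace every remaining 0 with the global minimum nonzero value."""
    vals = m.values
    arr = vals.to_numpy(dtype=float)
    nonzero = arr[arr != 0]
    if nonzero.size == 0:
        raise EmptyMatrixError("matrix has no nonzero values to impute from")
    fill = float(np.nanmin(nonzero))
    out = vals.where(vals != 0, other=fill)
    return m.with_values(out)


def log2_transform(m: OmicsMatrix) -> OmicsMatrix:
    """Elementwise log base 2; every value must be strictly positive."""
    arr = m.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        r, c = np.argwhere(arr <= 0)[0]
        raise DegenerateInputError(
            f"non-positive value at feature {m.values.index[r]!r}, "
            f"sample {m.values.columns[c]!r}: {arr[r, c]}"
        )
    return m.with_values(np.log2(m.values))


def collapse_probes(m: OmicsMatrix, probe_map: Mapping[str, str]) -> OmicsMatrix:
    """Average multi-probe features into one row per gene symbol.

    Output row order is the first-appearance order of symbols along the
    input's probe order. Every probe must be mapped.
    """
    unmapped = [p for p in m.values.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes missing from the probe map: {unmapped[:10]}")
    symbols = pd.Index([probe_map[p] for p in m.values.index], name="gene")
    grouped = m.values.groupby(symbols, sort=False).mean()
    return m.with_values(grouped)


def preprocess_pipeline(m: OmicsMatrix, probe_map: Mapping[str, str] | None = None,
                        log2: bool = True) -> OmicsMatrix:
    """drop-zeros -> impute -> (log2) -> (collapse probes)."""
    out = log2_transform(impute_zeros_min(drop_all_zero_rows(m))) if log2 \
        else impute_zeros_min(drop_all_zero_rows(m))
    if probe_map is not None:
        out = collapse_probes(out, probe_map)
    return out
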