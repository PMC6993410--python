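"""Core in-memory containers.

The whole pipeline operates on one shared container, :class:`OmicsMatrix`:
a named feature x sample matrix of real values (a :class:`pandas.DataFrame`
with feature IDs as the index and sample IDs as the columns) together with a
case/control label per sample. TF expression, gene expression and methylation
beta values all travel in this shape.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

CASE = "case"
CONTROL = "control"


@dataclass
class OmicsMatrix:
    """A feature x sample matrix with a case/control design.

    Parameters
    ----------
    values
        DataFrame of real values; index = feature IDs, columns = sample IDs.
        Both must be unique.
    labels
        Series mapping every sample ID to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ConfigError("duplicate feature IDs in matrix")
        if self.values.columns.has_duplicates:
            raise ConfigError("duplicate sample IDs in matrix")
        self.labels = pd.Series(self.labels)
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise ConfigError(f"samples without a group label: {missing[:5]}")
        bad = set(self.labels.unique()) - {CASE, CONTROL}
        if bad:
            raise ConfigError(f"unknown group labels: {sorted(bad)}")

    # -- convenience views -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def case_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == CASE]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.values.columns if self.labels[s] == CONTROL]

    def case_values(self) -> pd.DataFrame:
        """Sub-matrix restricted to case samples (column order preserved)."""
        return self.values[self.case_ids]

    def control_values(self) -> pd.DataFrame:
        return self.values[self.control_ids]

    def row(self, feature: str) -> pd.Series:
        return self.values.loc[feature]

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        """New container with the same labels and new values."""
        return OmicsMatrix(values=values, labels=self.labels)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values.to_numpy()).all())
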