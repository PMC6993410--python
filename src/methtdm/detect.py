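"""Stratified differential-correlation motif detection.

For every (differential methylation site) x (case-correlated TF-gene pair)
combination, case samples are ranked by the site's methylation level and
split into the bottom and top 40% (``floor(fraction * n_case)`` each). The
TF-gene Pearson correlation is computed inside each stratum; the motif
statistic is ``delta = r_high - r_low``. Combinations with |delta| strictly
above a threshold (default 0.7) are candidate motifs.

Significance is assessed by label permutation: the assignment between the
site's methylation values and the case samples is shuffled (the TF-gene
pairing stays intact — the null hypothesis is "methylation does not
modulate this pair", not "TF and gene are uncorrelated"), the strata are
re-derived and |delta| recomputed. The add-one estimator
``p = (1 + #{perm |delta| >= observed}) / (n_perm + 1)`` can never be 0.
Benjamini-Hochberg runs over all candidate motifs in one family and motifs
with q strictly below 0.05 are the significant ones.

Every motif's permutation stream is seeded from a stable hash of
``(master seed, site, tf, gene)``, so results do not depend on iteration
order.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .errors import ConfigError, DegenerateInputError
from .stats import bh_fdr, pearson

__all__ = [
    "Stratification",
    "stratify_samples",
    "delta_correlation",
    "candidate_motifs",
    "permutation_test",
    "detect_methtdms",
    "DetectionResult",
    "derive_motif_seed",
]

DEFAULT_FRACTION = 0.4
DEFAULT_DELTA_THRESHOLD = 0.7
DEFAULT_N_PERM = 1000
DEFAULT_FDR = 0.05
_REDRAW_CAP_FACTOR = 10


@dataclass(frozen=True)
class Stratification:
    """Bottom/top methylation strata of the case samples for one site."""

    site: str
    low_ids: tuple[str, ...]
    high_ids: tuple[str, ...]


def stratify_samples(meth_row: pd.Series, fraction: float = DEFAULT_FRACTION,
                     site: str = "") -> Stratification:
    """Split case samples into bottom/top ``floor(fraction * n)`` by value.

    Ties in methylation are broken by sample-ID lexicographic order, making
    the split fully deterministic.
    """
    if not 0 < fraction <= 0.5:
        raise ConfigError(f"fraction must be in (0, 0.5], got {fraction}")
    ids = np.asarray(meth_row.index, dtype=str)
    vals = meth_row.to_numpy(dtype=float)
    n = ids.size
    if n < 5:
        raise DegenerateInputError(f"need >= 5 case samples, got {n}")
    k = int(np.floor(fraction * n))
    order = np.lexsort((ids, vals))  # primary: value asc; ties: ID lexicographic
    return Stratification(
        site=site,
        low_ids=tuple(ids[order[:k]]),
        high_ids=tuple(ids[order[n - k:]]),
    )


def delta_correlation(tf_row: pd.Series, gene_row: pd.Series,
                      strat: Stratification) -> tuple[float, float, float]:
    """(r_low, r_high, delta = r_high - r_low) for one motif."""
    r_low = pearson(tf_row[list(strat.low_ids)], gene_row[list(strat.low_ids)])
    r_high = pearson(tf_row[list(strat.high_ids)], gene_row[list(strat.high_ids)])
    return r_low, r_high, r_high - r_low


def derive_motif_seed(master_seed: int, site: str, tf: str, gene: str) -> int:
    """Stable per-motif seed below 2**31, independent of iteration order."""
    digest = hashlib.sha256(f"{master_seed}:{site}:{tf}:{gene}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / denom
    r[denom == 0] = np.nan
    return r


def _perm_abs_deltas(x: np.ndarray, y: np.ndarray, m: np.ndarray, k: int,
                     n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """|delta| under ``n_perm`` random reassignments of methylation values.

    ``x``/``y``/``m`` must already be in lexicographic sample order so the
    stable sort's positional tie-break matches the observed rule.
    Permutations producing a degenerate (zero-variance) stratum are redrawn,
    capped at ``_REDRAW_CAP_FACTOR * n_perm`` total extra draws.
    """
    n = m.size
    out = np.full(n_perm, np.nan)
    pending = np.arange(n_perm)
    drawn = 0
    while pending.size:
        perms = rng.permuted(np.tile(np.arange(n), (pending.size, 1)), axis=1)
        drawn += pending.size
        mp = m[perms]
        idx = np.argsort(mp, axis=1, kind="stable")
        low, high = idx[:, :k], idx[:, n - k:]
        r_low = _rowwise_pearson(x[low], y[low])
        r_high = _rowwise_pearson(x[high], y[high])
        d = np.abs(r_high - r_low)
        ok = np.isfinite(d)
        out[pending[ok]] = d[ok]
        pending = pending[~ok]
        if pending.size and drawn > _REDRAW_CAP_FACTOR * n_perm:
            raise DegenerateInputError(
                "redraw cap exceeded: permutations keep producing degenerate strata"
            )
    return out


def _case_arrays(tf_m: OmicsMatrix, gene_m: OmicsMatrix, meth_m: OmicsMatrix,
                 ) -> tuple[list[str], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Case-sample sub-matrices with columns in lexicographic sample order."""
    case = sorted(tf_m.case_ids)
    if case != sorted(gene_m.case_ids) or case != sorted(meth_m.case_ids):
        raise ConfigError("matrices disagree on case sample IDs")
    return (case, tf_m.values[case], gene_m.values[case], meth_m.values[case])


def permutation_test(site: str, tf: str, gene: str,
                     tf_m: OmicsMatrix, gene_m: OmicsMatrix, meth_m: OmicsMatrix,
                     fraction: float = DEFAULT_FRACTION,
                     n_perm: int = DEFAULT_N_PERM,
                     seed: int = 0) -> float:
    """Add-one permutation p-value for one motif (deterministic given seed)."""
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    case, tf_case, gene_case, meth_case = _case_arrays(tf_m, gene_m, meth_m)
    x = tf_case.loc[tf].to_numpy(dtype=float)
    y = gene_case.loc[gene].to_numpy(dtype=float)
    m = meth_case.loc[site].to_numpy(dtype=float)
    strat = stratify_samples(pd.Series(m, index=case), fraction, site=site)
    r_low, r_high, delta = delta_correlation(
        pd.Series(x, index=case), pd.Series(y, index=case), strat)
    k = len(strat.low_ids)
    rng = np.random.default_rng(derive_motif_seed(seed, site, tf, gene))
    null = _perm_abs_deltas(x, y, m, k, n_perm, rng)
    return float((1 + (null >= abs(delta)).sum()) / (n_perm + 1))


def candidate_motifs(interactions: pd.DataFrame, sites: Sequence[str] | pd.DataFrame,
                     tf_m: OmicsMatrix, gene_m: OmicsMatrix, meth_m: OmicsMatrix,
                     fraction: float = DEFAULT_FRACTION,
                     delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
                     combos: Iterable[tuple[str, str, str]] | None = None,
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score the full (site x pair) cross — or an explicit combo list.

    Returns ``(candidates, tested, untestable)``: candidates are the tested
    rows with |delta| strictly above the threshold; untestable rows carry a
    reason (degenerate within-stratum variance).
    """
    if isinstance(sites, pd.DataFrame):
        sites = list(sites["site"])
    case, tf_case, gene_case, meth_case = _case_arrays(tf_m, gene_m, meth_m)
    if combos is None:
        pair_list = list(interactions[["tf", "gene"]].itertuples(index=False, name=None))
        combos = [(s, tf, gene) for s in sites for tf, gene in pair_list]
    rows, bad = [], []
    strat_cache: dict[str, Stratification] = {}
    for s, tf, gene in combos:
        strat = strat_cache.get(s)
        if strat is None:
            strat = stratify_samples(meth_case.loc[s].astype(float), fraction, site=s)
            strat_cache[s] = strat
        try:
            r_low, r_high, delta = delta_correlation(
                tf_case.loc[tf].astype(float), gene_case.loc[gene].astype(float),
                strat)
        except DegenerateInputError as exc:
            bad.append((s, tf, gene, str(exc)))
            continue
        rows.append((s, tf, gene, r_low, r_high, delta))
    tested = pd.DataFrame(
        rows, columns=["site", "tf", "gene", "r_low", "r_high", "delta"])
    candidates = tested[tested["delta"].abs() > delta_threshold].reset_index(drop=True)
    untestable = pd.DataFrame(bad, columns=["site", "tf", "gene", "reason"])
    return candidates, tested, untestable


@dataclass
class DetectionResult:
    significant: pd.DataFrame  # site, tf, gene, r_low, r_high, delta, p_perm, q
    candidates: pd.DataFrame   # same columns (all |delta| > threshold motifs)
    tested: pd.DataFrame       # every testable combination with its delta
    untestable: pd.DataFrame   # site, tf, gene, reason


def detect_methtdms(interactions: pd.DataFrame, sites: Sequence[str] | pd.DataFrame,
                    tf_m: OmicsMatrix, gene_m: OmicsMatrix, meth_m: OmicsMatrix,
                    fraction: float = DEFAULT_FRACTION,
                    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
                    n_perm: int = DEFAULT_N_PERM,
                    seed: int = 0,
                    fdr: float = DEFAULT_FDR,
                    combos: Iterable[tuple[str, str, str]] | None = None,
                    ) -> DetectionResult:
    """Full motif search: cross, candidate screen, permutations, BH."""
    candidates, tested, untestable = candidate_motifs(
        interactions, sites, tf_m, gene_m, meth_m, fraction, delta_threshold,
        combos=combos)
    case, tf_case, gene_case, meth_case = _case_arrays(tf_m, gene_m, meth_m)
    n_case = len(case)
    k = int(np.floor(fraction * n_case))
    pvals = []
    for row in candidates.itertuples(index=False):
        x = tf_case.loc[row.tf].to_numpy(dtype=float)
        y = gene_case.loc[row.gene].to_numpy(dtype=float)
        m = meth_case.loc[row.site].to_numpy(dtype=float)
        rng = np.random.default_rng(
            derive_motif_seed(seed, row.site, row.tf, row.gene))
        null = _perm_abs_deltas(x, y, m, k, n_perm, rng)
        pvals.append(float((1 + (null >= abs(row.delta)).sum()) / (n_perm + 1)))
    candidates = candidates.copy()
    candidates["p_perm"] = pvals
    candidates["q"] = bh_fdr(np.asarray(pvals)) if pvals else np.array([], dtype=float)
    candidates["abs_delta"] = candidates["delta"].abs()
    candidates = candidates.sort_values(
        ["q", "abs_delta", "site", "tf", "gene"],
        ascending=[True, False, True, True, True]).drop(columns="abs_delta")
    candidates = candidates.reset_index(drop=True)
    significant = candidates[candidates["q"] < fdr].reset_index(drop=True)
    return DetectionResult(significant=significant, candidates=candidates,
                           tested=tested, untestable=untestable)
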