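"""Elementary statistics used by every pipeline stage.

Pearson correlation, the classical (pooled-variance) two-sample Student t
test, Benjamini-Hochberg step-up FDR adjustment, and an ordinary
least-squares fit of log10(node count) on log10(degree) for scale-free
checks of network degree distributions. Computation is delegated to
scipy/statsmodels; this module adds the input validation and the result
containers the rest of the pipeline relies on.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError

__all__ = [
    "TestResult",
    "FitResult",
    "pearson",
    "student_t_two_sample",
    "bh_fdr",
    "log_log_fit",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r_squared: float


def _as_1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if not np.isfinite(a).all():
        raise DegenerateInputError(f"{name} contains non-finite values")
    return a


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3).

    Raises
    ------
    DegenerateInputError
        If either vector is constant: a correlation is undefined there and
        silently returning 0 or NaN would corrupt downstream screens.
    """
    a, b = _as_1d(x, "x"), _as_1d(y, "y")
    if a.size != b.size:
        raise DegenerateInputError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise DegenerateInputError(f"need >= 3 observations, got {a.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("zero variance in at least one vector")
    r = sps.pearsonr(a, b).statistic
    # guard against tiny numerical overshoot
    return float(min(1.0, max(-1.0, r)))


def student_t_two_sample(a, b, welch: bool = False) -> TestResult:
    """Two-sample t test, classical pooled-variance form by default.

    ``df = n_a + n_b - 2`` and a two-sided p-value from the t distribution.
    Set ``welch=True`` for the unequal-variance (Welch) variant.
    """
    x, y = _as_1d(a, "a"), _as_1d(b, "b")
    if x.size < 2 or y.size < 2:
        raise DegenerateInputError("each group needs >= 2 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise DegenerateInputError("zero pooled variance: both groups constant")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    arr = _as_1d(p, "p")
    if arr.size == 0:
        return arr
    if (arr < 0).any() or (arr > 1).any():
        raise DegenerateInputError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


def log_log_fit(degrees) -> FitResult:
    """OLS fit of log10(count of nodes with degree k) on log10(k).

    Uses raw counts over the distinct degrees present (zero-count degrees are
    omitted; their log is undefined). Degree 0 nodes are excluded for the
    same reason.
    """
    d = np.asarray(degrees)
    if d.size == 0:
        raise DegenerateInputError("empty degree sequence")
    if (d < 0).any():
        raise DegenerateInputError("degrees must be non-negative integers")
    ks, counts = np.unique(d[d > 0], return_counts=True)
    if ks.size < 2:
        raise DegenerateInputError(
            "need >= 2 distinct positive degree values for a log-log fit"
        )
    res = sps.linregress(np.log10(ks), np.log10(counts))
    return FitResult(slope=float(res.slope), intercept=float(res.intercept),
                     r_squared=float(res.rvalue ** 2))
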