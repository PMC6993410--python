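"""Screens that define the analysis universe.

Two filters feed the motif search:

* catalog TF-gene pairs whose expression correlates in *case samples only*
  (|Pearson r| strictly above a threshold, default 0.25), and
* methylation sites differential between case and control by the pooled
  two-sample t test with BH FDR strictly below a threshold (default 0.05).

Pairs or sites with degenerate variance are reported separately, never
silently dropped and never allowed to crash a run.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .errors import DegenerateInputError
from .stats import bh_fdr, pearson, student_t_two_sample

__all__ = [
    "InteractionScreenResult",
    "DifferentialMethylationResult",
    "pe_specific_interactions",
    "differential_methylation",
]

DEFAULT_R_THRESHOLD = 0.25
DEFAULT_Q_THRESHOLD = 0.05


@dataclass
class InteractionScreenResult:
    retained: pd.DataFrame   # tf, gene, r_case — sorted |r| desc, ties (tf, gene)
    scored: pd.DataFrame     # all scoreable pairs
    skipped: pd.DataFrame    # tf, gene, reason


@dataclass
class DifferentialMethylationResult:
    retained: pd.DataFrame   # site, t, p, q, mean_case, mean_control
    tested: pd.DataFrame     # all testable sites with the same columns
    degenerate: pd.DataFrame  # site, reason


def pe_specific_interactions(tf_m: OmicsMatrix, gene_m: OmicsMatrix,
                             catalog: pd.DataFrame,
                             r_threshold: float = DEFAULT_R_THRESHOLD,
                             ) -> InteractionScreenResult:
    """Score every catalog pair by case-sample Pearson r; keep |r| > threshold."""
    case = tf_m.case_ids
    if len(case) < 3:
        raise DegenerateInputError("need >= 3 case samples for correlation")
    tf_case = tf_m.case_values()
    gene_case = gene_m.case_values()
    rows, skipped = [], []
    for tf, gene in catalog[["tf", "gene"]].itertuples(index=False):
        if tf not in tf_case.index:
            skipped.append((tf, gene, "tf missing from TF matrix"))
            continue
        if gene not in gene_case.index:
            skipped.append((tf, gene, "gene missing from gene matrix"))
            continue
        try:
            r = pearson(tf_case.loc[tf], gene_case.loc[gene])
        except DegenerateInputError as exc:
            skipped.append((tf, gene, str(exc)))
            continue
        rows.append((tf, gene, r))
    scored = pd.DataFrame(rows, columns=["tf", "gene", "r_case"])
    scored = scored.sort_values(
        by=["r_case", "tf", "gene"],
        key=lambda c: -c.abs() if c.name == "r_case" else c,
    ).reset_index(drop=True)
    retained = scored[scored["r_case"].abs() > r_threshold].reset_index(drop=True)
    return InteractionScreenResult(
        retained=retained,
        scored=scored,
        skipped=pd.DataFrame(skipped, columns=["tf", "gene", "reason"]),
    )


def differential_methylation(meth_m: OmicsMatrix,
                             q_threshold: float = DEFAULT_Q_THRESHOLD,
                             ) -> DifferentialMethylationResult:
    """Per-site case-vs-control t test with one global BH family."""
    case = meth_m.case_values().to_numpy(dtype=float)
    ctrl = meth_m.control_values().to_numpy(dtype=float)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise DegenerateInputError("each group needs >= 2 samples")
    rows, degenerate = [], []
    for i, site in enumerate(meth_m.feature_ids):
        try:
            res = student_t_two_sample(case[i], ctrl[i])
        except DegenerateInputError as exc:
            degenerate.append((site, str(exc)))
            continue
        rows.append((site, res.statistic, res.p_value,
                     float(case[i].mean()), float(ctrl[i].mean())))
    tested = pd.DataFrame(rows, columns=["site", "t", "p", "mean_case",
                                         "mean_control"])
    if len(tested):
        tested["q"] = bh_fdr(tested["p"].to_numpy())
    else:
        tested["q"] = np.array([], dtype=float)
    tested = tested[["site", "t", "p", "q", "mean_case", "mean_control"]]
    tested = tested.sort_values(["q", "p", "site"]).reset_index(drop=True)
    retained = tested[tested["q"] < q_threshold].reset_index(drop=True)
    return DifferentialMethylationResult(
        retained=retained,
        tested=tested,
        degenerate=pd.DataFrame(degenerate, columns=["site", "reason"]),
    )
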