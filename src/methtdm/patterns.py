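"""Six-way regulation-pattern classification of significant motifs.

The low-methylation stratum is the baseline: ``r_low`` calls the TF's
unperturbed direction (activation if positive, inhibition if negative) and
``r_high`` shows what methylation does to it. The six labels:

==============  =======================================================
label            meaning (baseline -> high-methylation stratum)
==============  =======================================================
relax_*          same sign, magnitude shrinks
intensify_*      same sign, magnitude grows
reverse_activation   inhibition (r_low < 0) flips to activation
reverse_inhibition   activation (r_low > 0) flips to inhibition
==============  =======================================================

A motif whose |r_low| falls below ``tau`` has no callable baseline
direction and is reported as unclassifiable rather than forced into a
label. ``|r_high| == |r_low|`` exactly resolves to the relax label.
"""
from __future__ import annotations

import itertools

import pandas as pd

from .errors import UnclassifiableMotifError

PATTERN_LABELS = (
    "relax_inhibition",
    "intensify_inhibition",
    "relax_activation",
    "intensify_activation",
    "reverse_activation",
    "reverse_inhibition",
)

DEFAULT_TAU = 0.25


def classify_pattern(r_low: float, r_high: float, tau: float = DEFAULT_TAU) -> str:
    """Assign one of the six regulation-pattern labels."""
    if abs(r_low) < tau:
        raise UnclassifiableMotifError(
            f"baseline correlation |r_low|={abs(r_low):.3f} below tau={tau}"
        )
    if r_low < 0:  # baseline inhibition
        if r_high > 0:
            return "reverse_activation"
        if abs(r_high) > abs(r_low):
            return "intensify_inhibition"
        return "relax_inhibition"
    # baseline activation
    if r_high < 0:
        return "reverse_inhibition"
    if abs(r_high) > abs(r_low):
        return "intensify_activation"
    return "relax_activation"


def classify_motifs(motifs: pd.DataFrame, tau: float = DEFAULT_TAU
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label a motif table (needs r_low / r_high columns).

    Returns ``(classified, unclassifiable)``; the first gains a ``pattern``
    column, the second keeps the rows whose baseline direction is not
    callable (they are excluded from every summary).
    """
    labels, ok = [], []
    for _, row in motifs.iterrows():
        try:
            labels.append(classify_pattern(row["r_low"], row["r_high"], tau))
            ok.append(True)
        except UnclassifiableMotifError:
            ok.append(False)
    mask = pd.Series(ok, index=motifs.index)
    classified = motifs[mask].copy()
    classified["pattern"] = labels
    return classified, motifs[~mask].copy()


def pattern_distribution(motifs: pd.DataFrame) -> pd.DataFrame:
    """Motif count and fraction per label, all six labels always present."""
    counts = motifs["pattern"].value_counts() if len(motifs) else pd.Series(dtype=int)
    total = int(counts.sum())
    rows = []
    for label in PATTERN_LABELS:
        n = int(counts.get(label, 0))
        rows.append({
            "pattern": label,
            "count": n,
            "fraction": (n / total) if total else float("nan"),
        })
    return pd.DataFrame(rows)


def _pair_key(row) -> str:
    return f"{row['tf']}::{row['gene']}"


def cross_pattern_overlap(motifs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Shared TF-gene pairs and shared sites between every two labels.

    An element belongs to a label if at least one motif with that label
    involves it. Returns symmetric 6x6 matrices whose diagonals are the
    per-label element totals.
    """
    pair_sets = {lab: set() for lab in PATTERN_LABELS}
    site_sets = {lab: set() for lab in PATTERN_LABELS}
    for _, row in motifs.iterrows():
        pair_sets[row["pattern"]].add(_pair_key(row))
        site_sets[row["pattern"]].add(row["site"])
    out = {}
    for name, sets in (("pairs", pair_sets), ("sites", site_sets)):
        mat = pd.DataFrame(0, index=list(PATTERN_LABELS), columns=list(PATTERN_LABELS))
        for a, b in itertools.combinations_with_replacement(PATTERN_LABELS, 2):
            n = len(sets[a] & sets[b]) if a != b else len(sets[a])
            mat.loc[a, b] = n
            mat.loc[b, a] = n
        out[name] = mat
    return out


def element_pattern_frequency(motifs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Distinct-label count per site and per TF-gene pair."""
    out = {}
    for name, key in (("sites", lambda r: r["site"]), ("pairs", _pair_key)):
        tally: dict[str, set] = {}
        for _, row in motifs.iterrows():
            tally.setdefault(key(row), set()).add(row["pattern"])
        df = pd.DataFrame(
            sorted(((k, len(v)) for k, v in tally.items()),
                   key=lambda t: (-t[1], t[0])),
            columns=["element", "n_patterns"],
        )
        out[name] = df
    return out


def fraction_exceeding(freq: pd.DataFrame, k: int) -> float:
    """Fraction of elements participating in more than ``k`` distinct labels."""
    if len(freq) == 0:
        return float("nan")
    return float((freq["n_patterns"] > k).mean())
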