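"""Label every significant motif with one of the six regulation patterns
(relax / intensify / reverse x activation / inhibition, read off the low-
vs high-methylation stratum correlations) and summarize: the pattern
distribution, cross-pattern overlaps of pairs and sites, and how many
distinct patterns each site and pair participates in."""
import argparse
import json
from pathlib import Path

import pandas as pd

from methtdm.cli import classify


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results / "patterns"
    classify.callback(
        motifs_path=str(args.results / "motifs" / "methtdms.tsv"),
        tau=0.25, outdir=str(out))

    dist = pd.read_csv(out / "pattern_distribution.tsv", sep="\t")
    print(dist.to_string(index=False))
    summary = json.loads((out / "pattern_summary.json").read_text())
    print(f"sites in >2 patterns: {summary['site_frac_gt2_patterns']:.2f}; "
          f"pairs in >2 patterns: {summary['pair_frac_gt2_patterns']:.2f}")


if __name__ == "__main__":
    main()
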