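"""Detect methylation-TF-gene motifs: for every (differential site,
retained pair) combination, rank case samples by the site's methylation,
correlate the pair inside the bottom and top 40% strata, keep candidates
with |delta r| > 0.7, and assess each by 1000 methylation-reassignment
permutations with BH control at 0.05."""
import argparse
from pathlib import Path

import pandas as pd

from methtdm.cli import detect


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-perm", type=int, default=1000)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    cand = args.results / "candidates"
    out = args.results / "motifs"
    detect.callback(
        inter_path=str(cand / "interactions.tsv"),
        sites_path=str(cand / "diff_sites.tsv"),
        tf_path=str(args.results / "tf_preprocessed.tsv"),
        gene_path=str(args.results / "gene_preprocessed.tsv"),
        meth_path=str(args.results / "meth_preprocessed.tsv"),
        labels_path=str(args.results / "data" / "labels.tsv"),
        fraction=0.4, delta_threshold=0.7, n_perm=args.n_perm,
        seed=args.seed, fdr=0.05, outdir=str(out))

    sig = pd.read_csv(out / "methtdms.tsv", sep="\t")
    print("strongest motifs:")
    print(sig.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
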