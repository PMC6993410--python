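"""Screen the analysis universe: catalog TF-gene pairs correlated in case
samples (|Pearson r| > 0.25) and methylation sites differential between
case and control (pooled t test, BH q < 0.05)."""
import argparse
from pathlib import Path

import pandas as pd

from methtdm.cli import candidates


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.results / "data"
    out = args.results / "candidates"
    candidates.callback(
        tf_path=str(args.results / "tf_preprocessed.tsv"),
        gene_path=str(args.results / "gene_preprocessed.tsv"),
        meth_path=str(args.results / "meth_preprocessed.tsv"),
        labels_path=str(data / "labels.tsv"),
        catalog_path=str(data / "catalog.tsv"),
        r_threshold=0.25, q_threshold=0.05, outdir=str(out))

    inter = pd.read_csv(out / "interactions.tsv", sep="\t")
    print("strongest case-correlated pairs:")
    print(inter.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
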