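"""Interpret the motif set: Fisher enrichment of motif TFs+genes against
the simulated gene-set library (GO-style q < 0.01 and KEGG-style q < 0.05
cuts), and the drug-gene bipartite network over motif genes with its
degree-ranked repurposing shortlist."""
import argparse
from pathlib import Path

import pandas as pd

from methtdm.cli import drugs, enrich


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.results / "data"
    motifs = str(args.results / "patterns" / "methtdms_classified.tsv")

    for label, fdr in (("go_style", 0.01), ("kegg_style", 0.05)):
        enrich.callback(
            motifs_path=motifs, gmt_path=str(data / "gene_sets.gmt"),
            background_path=None, tf_path=str(data / "tf.tsv"),
            gene_path=str(data / "gene.tsv"), fdr=fdr,
            outdir=str(args.results / f"enrichment_{label}"))

    drugs.callback(motifs_path=motifs,
                   catalog_path=str(data / "drug_catalog.tsv"),
                   top=10, outdir=str(args.results / "drugs"))
    top = pd.read_csv(args.results / "drugs" / "top_drugs.tsv", sep="\t")
    print("degree-ranked repurposing candidates:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
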