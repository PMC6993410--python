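"""Build the bipartite motif network (methylation-site nodes vs TF-gene-
pair nodes, one edge per significant motif), fit the degree distribution
on log-log axes, run MCODE for dense core modules, and extract the ego
subnetwork of the best-connected site. Saves a degree-distribution figure.

On a cohort this small the bipartite network is sparse; MCODE (plugin
defaults) only reports a module when the core sites and pairs form a
reasonably balanced biclique, so an empty module list is a legitimate
outcome for some seeds.
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from methtdm.cli import ego, network


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    out = args.results / "network"
    network.callback(
        motifs_path=str(args.results / "patterns" / "methtdms_classified.tsv"),
        mcode_degree_cutoff=2, mcode_node_score_cutoff=0.2, mcode_k_core=2,
        mcode_max_depth=100, mcode_haircut=True, outdir=str(out))

    fit = json.loads((out / "scale_free_fit.json").read_text())
    print(f"log-log degree fit: slope={fit['slope']}, R^2={fit['r_squared']}")
    modules = pd.read_csv(out / "modules.tsv", sep="\t")
    if len(modules):
        top = modules.iloc[0]
        print(f"core module: score {top['score']:.2f}, "
              f"{top['n_nodes']} nodes")
    else:
        print("no dense module at MCODE defaults on this seed")

    sites = pd.read_csv(out / "site_degree.tsv", sep="\t")
    if len(sites):
        hub = sites.iloc[0]["node"]
        ego.callback(
            motifs_path=str(args.results / "patterns"
                            / "methtdms_classified.tsv"),
            node=hub, radius=1, out=str(out / "hub_site_ego.tsv"))

    degrees = pd.read_csv(out / "degree.tsv", sep="\t")
    counts = degrees["degree"].value_counts().sort_index()
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axis = plt.subplots(figsize=(4, 3))
        axis.scatter(counts.index, counts.values)
        axis.set_xscale("log")
        axis.set_yscale("log")
        axis.set_xlabel("degree k")
        axis.set_ylabel("nodes with degree k")
        fig.tight_layout()
        figdir = args.results / "figures"
        figdir.mkdir(parents=True, exist_ok=True)
        fig.savefig(figdir / "degree_distribution.png", dpi=150)
    except ImportError:
        pass


if __name__ == "__main__":
    main()
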