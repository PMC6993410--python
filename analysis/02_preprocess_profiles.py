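"""Clean the three profiles: drop all-zero features, impute residual zeros
with the global minimum nonzero value, and log2-transform. The synthetic
expression is simulated on an intensity scale, so the log2 step restores
the latent Gaussian scale the planted correlations live on; methylation is
transformed too (its downstream use is rank-based, so this is harmless)."""
import argparse
from pathlib import Path

from methtdm.cli import preprocess


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()
    data = args.results / "data"
    for name in ("tf", "gene", "meth"):
        preprocess.callback(
            matrix_path=str(data / f"{name}.tsv"),
            labels_path=str(data / "labels.tsv"),
            probe_map=None, log2=True,
            out=str(args.results / f"{name}_preprocessed.tsv"))


if __name__ == "__main__":
    main()
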