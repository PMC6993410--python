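"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
matrix TSV      first column = feature ID, header row = sample IDs
labels TSV      columns: sample_id, group (case/control)
pairs TSV       two columns, e.g. (tf, gene) or (drug, gene)
GMT             one gene set per line: name <TAB> description <TAB> genes...
ground truth    JSON, written by the simulator
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .containers import OmicsMatrix

FLOAT_FORMAT = "%.10g"


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return pd.Series(df["group"].values, index=df["sample_id"].values, name="group")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "group": labels.values}).to_csv(
        path, sep="\t", index=False
    )


def load_omics(matrix_path: str | Path, labels_path: str | Path) -> OmicsMatrix:
    return OmicsMatrix(values=read_matrix(matrix_path), labels=read_labels(labels_path))


def read_pairs(path: str | Path, columns: tuple[str, str] = ("tf", "gene")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    got = tuple(df.columns[:2])
    if got != columns:
        df = df.rename(columns=dict(zip(got, columns)))
    return df[list(columns)]


def write_pairs(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic deterministic TSV writer for result tables."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            name, _desc, genes = parts[0], parts[1], parts[2:]
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    probes, symbols = df.columns[:2]
    return dict(zip(df[probes], df[symbols]))


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
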