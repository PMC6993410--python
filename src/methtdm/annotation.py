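"""Downstream interpretation: gene-set enrichment and the drug network.

Enrichment is a one-sided Fisher exact test of the overlap between a query
gene list (by default the union of TFs and genes in significant motifs) and
each GMT set, against a configurable background universe, with BH FDR
across all tested sets. Strict per-library q thresholds apply downstream
(conventionally 0.01 for GO-style, 0.05 for KEGG-style libraries).

The drug network restricts a drug->gene catalog to genes/TFs appearing in
significant motifs and ranks drugs by degree; the top of that ranking is
the repurposing shortlist.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy.stats import fisher_exact

from .errors import ConfigError
from .stats import bh_fdr

__all__ = [
    "fisher_enrichment",
    "filter_enriched",
    "motif_gene_universe",
    "build_drug_network",
    "top_drugs",
]


def motif_gene_universe(motifs: pd.DataFrame) -> set[str]:
    """Union of TFs and genes appearing in a motif table."""
    return set(motifs["tf"]) | set(motifs["gene"])


def fisher_enrichment(query_genes: Iterable[str],
                      gmt: Mapping[str, Iterable[str]],
                      background: Iterable[str]) -> pd.DataFrame:
    """One record per set with >= 1 query overlap, BH-adjusted.

    Sets are intersected with the background first; the query must be a
    subset of the background. Sorted by p ascending, ties by set name.
    """
    bg = set(background)
    query = set(query_genes)
    if not query or not bg:
        raise ConfigError("query and background must be nonempty")
    outside = query - bg
    if outside:
        raise ConfigError(
            f"query genes outside the background: {sorted(outside)[:5]}")
    rows = []
    for name in sorted(gmt):
        members = set(gmt[name]) & bg
        overlap = len(members & query)
        if overlap == 0:
            continue
        a = overlap                          # in query and in set
        b = len(query) - overlap             # in query only
        c = len(members) - overlap           # in set only
        d = len(bg) - a - b - c              # in neither
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((name, a, len(members), len(query), len(bg),
                     float(odds), float(p)))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                     "query_size", "background_size",
                                     "odds_ratio", "p"])
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values(["p", "set_name"]).reset_index(drop=True)


def filter_enriched(records: pd.DataFrame, q_threshold: float) -> pd.DataFrame:
    """Strict ``q < q_threshold`` filter."""
    if len(records) == 0:
        return records
    return records[records["q"] < q_threshold].reset_index(drop=True)


def build_drug_network(motifs: pd.DataFrame, drug_catalog: pd.DataFrame
                       ) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite drug/gene graph over motif genes, plus the degree ranking.

    Catalog edges whose gene is not a motif TF/gene are dropped; duplicate
    rows collapse to one edge. Returns ``(graph, ranking)`` with the
    ranking sorted by degree descending, ties by drug name.
    """
    genes = motif_gene_universe(motifs)
    g = nx.Graph()
    for drug, gene in drug_catalog[["drug", "gene"]].itertuples(index=False):
        if gene not in genes:
            continue
        if drug not in g:
            g.add_node(drug, role="drug")
        if gene not in g:
            g.add_node(gene, role="gene")
        g.add_edge(drug, gene)
    rows = [(n, g.degree(n)) for n in g.nodes if g.nodes[n]["role"] == "drug"]
    ranking = pd.DataFrame(rows, columns=["drug", "degree"]).sort_values(
        ["degree", "drug"], ascending=[False, True]).reset_index(drop=True)
    return g, ranking


def top_drugs(ranking: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    return ranking.head(n).reset_index(drop=True)
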