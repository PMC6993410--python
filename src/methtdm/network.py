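"""Bipartite motif network, degree analysis and dense-module detection.

The network has one node per distinct methylation site and one node per
distinct TF-gene pair; each significant motif contributes one (site, pair)
edge carrying its delta, q and pattern. Dense regions are found with a
from-scratch MCODE (Molecular Complex Detection): nodes are weighted by
``k * density`` of the highest k-core of their closed neighborhood, modules
grow greedily from high-weight seeds, and the score of a module is
``density * node count``. The whole procedure is deterministic: every tie
is broken lexicographically.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .errors import ConfigError
from .stats import FitResult, log_log_fit

__all__ = [
    "pair_node",
    "build_network",
    "degree_table",
    "Module",
    "mcode_modules",
    "extract_ego",
]

PAIR_SEP = "::"


def pair_node(tf: str, gene: str) -> str:
    return f"{tf}{PAIR_SEP}{gene}"


def build_network(motifs: pd.DataFrame) -> nx.Graph:
    """Bipartite site/pair graph with one edge per motif.

    ``motifs`` needs columns site, tf, gene and optionally delta, q,
    pattern (copied onto the edges). Duplicate (site, tf, gene) keys are an
    error — each motif is unique by construction.
    """
    keys = list(zip(motifs["site"], motifs["tf"], motifs["gene"]))
    if len(set(keys)) != len(keys):
        raise ConfigError("duplicate (site, tf, gene) motif keys")
    g = nx.Graph()
    for row in motifs.itertuples(index=False):
        p = pair_node(row.tf, row.gene)
        if row.site not in g:
            g.add_node(row.site, role="site")
        if p not in g:
            g.add_node(p, role="pair", tf=row.tf, gene=row.gene)
        attrs = {}
        for col in ("delta", "q", "pattern"):
            if hasattr(row, col):
                attrs[col] = getattr(row, col)
        g.add_edge(row.site, p, **attrs)
    g.graph["n_motifs"] = len(motifs)
    g.graph["n_sites"] = len(set(motifs["site"]))
    g.graph["n_pairs"] = len(set(zip(motifs["tf"], motifs["gene"])))
    g.graph["n_tfs"] = len(set(motifs["tf"]))
    g.graph["n_genes"] = len(set(motifs["gene"]))
    return g


def degree_table(net: nx.Graph) -> tuple[pd.DataFrame, FitResult, pd.DataFrame]:
    """Per-node degrees, the log-log scale-free fit, and the site-only view."""
    if net.number_of_nodes() == 0:
        raise ConfigError("empty network")
    rows = [(n, net.nodes[n].get("role", "?"), d) for n, d in net.degree()]
    df = pd.DataFrame(rows, columns=["node", "role", "degree"])
    df = df.sort_values(["degree", "node"], ascending=[False, True]
                        ).reset_index(drop=True)
    fit = log_log_fit(df["degree"].to_numpy())
    site_view = df[df["role"] == "site"].reset_index(drop=True)
    return df, fit, site_view


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Module:
    nodes: tuple[str, ...]  # sorted
    score: float
    rank: int
    seed: str


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n <= 1:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, induced subgraph of the highest k-core); (0, g) if edgeless."""
    if g.number_of_edges() == 0:
        return 0, g
    core = nx.core_number(g)
    kmax = max(core.values())
    nodes = [n for n, c in core.items() if c >= kmax]
    return kmax, g.subgraph(nodes)


def _node_weights(net: nx.Graph, degree_cutoff: int) -> dict[str, float]:
    weights: dict[str, float] = {}
    for v in net.nodes:
        if net.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        nbhd = net.subgraph([v, *net.neighbors(v)])
        k, core = _highest_k_core(nbhd)
        weights[v] = k * _density(core)
    return weights


def mcode_modules(net: nx.Graph, degree_cutoff: int = 2,
                  node_score_cutoff: float = 0.2, k_core: int = 2,
                  max_depth: int = 100, haircut: bool = True,
                  fluff: bool = False) -> list[Module]:
    """Ranked dense modules by the MCODE procedure (plugin defaults).

    1. weight every node by ``k * density`` of the highest k-core of its
       closed neighborhood (nodes under ``degree_cutoff`` weigh 0);
    2. from each unseen node in weight order, breadth-first admit unseen
       neighbors whose weight >= seed weight * (1 - node_score_cutoff), up
       to ``max_depth`` levels;
    3. discard modules without a ``k_core``-core; ``haircut`` strips
       degree-1 nodes; score = density * node count.

    ``fluff`` is accepted for interface parity but not implemented.
    """
    if fluff:
        raise NotImplementedError("the 'fluff' post-processing option is not implemented")
    if net.number_of_nodes() == 0:
        return []
    weights = _node_weights(net, degree_cutoff)
    order = sorted(net.nodes, key=lambda v: (-weights[v], str(v)))
    seen: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in order:
        if seed in seen or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1 - node_score_cutoff)
        module = {seed}
        seen.add(seed)
        frontier = [seed]
        for _ in range(max_depth):
            nxt = []
            for v in frontier:
                for w in net.neighbors(v):
                    if w in seen or w in module:
                        continue
                    if weights[w] >= threshold:
                        module.add(w)
                        seen.add(w)
                        nxt.append(w)
            if not nxt:
                break
            frontier = nxt
        raw.append((seed, module))

    modules: list[Module] = []
    for seed, nodes in raw:
        sub = net.subgraph(nodes).copy()
        if sub.number_of_edges() == 0:
            continue
        kmax, _ = _highest_k_core(sub)
        if kmax < k_core:
            continue
        if haircut:
            keep = [v for v in sub.nodes if sub.degree(v) > 1]
            sub = sub.subgraph(keep).copy()
            if sub.number_of_nodes() == 0:
                continue
        if not nx.is_connected(sub):
            # keep the component holding the seed (or the largest, if the
            # haircut removed the seed itself)
            comps = sorted(nx.connected_components(sub),
                           key=lambda c: (-len(c), tuple(sorted(map(str, c)))))
            chosen = next((c for c in comps if seed in c), comps[0])
            sub = sub.subgraph(chosen).copy()
        score = _density(sub) * sub.number_of_nodes()
        modules.append(Module(nodes=tuple(sorted(map(str, sub.nodes))),
                              score=score, rank=0, seed=seed))

    modules.sort(key=lambda m: (-m.score, m.nodes))
    return [Module(nodes=m.nodes, score=m.score, rank=i + 1, seed=m.seed)
            for i, m in enumerate(modules)]


def extract_ego(net: nx.Graph, node_id: str, radius: int = 1) -> nx.Graph:
    """Induced subgraph on a node and everything within ``radius`` hops."""
    if node_id not in net:
        raise KeyError(f"node {node_id!r} not in network")
    return nx.ego_graph(net, node_id, radius=radius)
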