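import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methtdm.errors import ConfigError, DegenerateInputError
from methtdm.network import (build_network, degree_table, extract_ego,
                             mcode_modules, pair_node)

from oracles import degrees_brute, ego_nodes_brute


def motif_df(rows):
    return pd.DataFrame(rows, columns=["site", "tf", "gene"])


class TestBuildNetwork:
    def test_shared_site_degree(self):
        g = build_network(motif_df([("s1", "T1", "G1"), ("s1", "T2", "G2"),
                                    ("s1", "T3", "G3")]))
        assert g.degree("s1") == 3
        assert g.graph["n_pairs"] == 3 and g.graph["n_sites"] == 1

    def test_empty_motifs(self):
        g = build_network(motif_df([]))
        assert g.number_of_nodes() == 0

    def test_hand_drawn_fixture_counts(self):
        rows = [("s1", "T1", "G1"), ("s1", "T1", "G2"), ("s2", "T1", "G1"),
                ("s2", "T2", "G3"), ("s3", "T2", "G3"), ("s3", "T3", "G4"),
                ("s4", "T3", "G4"), ("s4", "T1", "G1"), ("s5", "T4", "G5"),
                ("s5", "T1", "G2")]
        g = build_network(motif_df(rows))
        # 5 sites + 5 distinct pairs; one edge per motif
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 10
        assert g.graph["n_tfs"] == 4 and g.graph["n_genes"] == 5

    def test_duplicate_motif_keys_rejected(self):
        with pytest.raises(ConfigError):
            build_network(motif_df([("s1", "T1", "G1"), ("s1", "T1", "G1")]))

    def test_bipartite_roles(self):
        g = build_network(motif_df([("s1", "T1", "G1")]))
        assert g.nodes["s1"]["role"] == "site"
        assert g.nodes[pair_node("T1", "G1")]["role"] == "pair"


class TestDegreeTable:
    def test_star_fixture_fits_exactly(self):
        rows = [("s1", f"T{i}", f"G{i}") for i in range(5)]
        df, fit, site_view = degree_table(build_network(motif_df(rows)))
        assert fit.r_squared == pytest.approx(1.0)
        assert site_view["degree"].tolist() == [5]

    def test_degrees_match_brute_adjacency_count(self):
        rng = np.random.default_rng(3)
        rows = [(f"s{rng.integers(6)}", f"T{rng.integers(4)}",
                 f"G{rng.integers(4)}") for _ in range(25)]
        df = motif_df(rows).drop_duplicates()
        g = build_network(df)
        brute = degrees_brute(list(g.edges()), list(g.nodes()))
        table, _, _ = degree_table(g)
        for row in table.itertuples():
            assert brute[row.node] == row.degree

    def test_handshake_identity(self):
        rng = np.random.default_rng(9)
        rows = [(f"s{rng.integers(10)}", f"T{rng.integers(6)}",
                 f"G{rng.integers(6)}") for _ in range(40)]
        df = motif_df(rows).drop_duplicates()
        g = build_network(df)
        table, _, sites = degree_table(g)
        pair_sum = table[table["role"] == "pair"]["degree"].sum()
        assert sites["degree"].sum() == pair_sum == len(df)


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

def k5_plus_pendant():
    g = nx.complete_graph(5)
    g = nx.relabel_nodes(g, {i: f"k{i}" for i in range(5)})
    g.add_edges_from([("k0", "p1"), ("p1", "p2"), ("p2", "p3")])
    return g


def mcode_reference(net, degree_cutoff=2, node_score_cutoff=0.2, k_core=2,
                    haircut=True):
    """Independent re-derivation of the MCODE procedure (set-based fixpoint
    expansion instead of the package's level-by-level BFS)."""
    def density(sub):
        n = sub.number_of_nodes()
        return 0.0 if n <= 1 else 2 * sub.number_of_edges() / (n * (n - 1))

    def highest_core(sub):
        if sub.number_of_edges() == 0:
            return 0, sub
        cn = nx.core_number(sub)
        kmax = max(cn.values())
        return kmax, sub.subgraph([v for v, c in cn.items() if c >= kmax])

    w = {}
    for v in net:
        if net.degree(v) < degree_cutoff:
            w[v] = 0.0
            continue
        k, core = highest_core(net.subgraph([v, *net.neighbors(v)]))
        w[v] = k * density(core)

    seen, found = set(), []
    for seed in sorted(net, key=lambda v: (-w[v], str(v))):
        if seed in seen or w[seed] <= 0:
            continue
        thr = w[seed] * (1 - node_score_cutoff)
        module = {seed}
        changed = True
        while changed:
            changed = False
            for v in sorted(module):
                for u in net.neighbors(v):
                    if u not in module and u not in seen and w[u] >= thr:
                        module.add(u)
                        changed = True
        seen |= module
        sub = net.subgraph(module).copy()
        kmax, _ = highest_core(sub)
        if kmax < k_core:
            continue
        if haircut:
            sub = sub.subgraph([v for v in sub if sub.degree(v) > 1]).copy()
            if not sub:
                continue
        if not nx.is_connected(sub):
            comps = sorted(nx.connected_components(sub),
                           key=lambda c: (-len(c), tuple(sorted(map(str, c)))))
            sub = sub.subgraph(next((c for c in comps if seed in c),
                                    comps[0])).copy()
        found.append((tuple(sorted(map(str, sub))), density(sub) * len(sub)))
    found.sort(key=lambda t: (-t[1], t[0]))
    return found


def planted_block_graph(seed, n_background=60, n_block=8, p_bg=0.05, p_block=0.9):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(n_background))
    for i in range(n_background):
        for j in range(i + 1, n_background):
            if rng.random() < p_bg:
                g.add_edge(i, j)
    block = list(range(n_block))  # first nodes form the dense block
    for i in block:
        for j in block:
            if i < j and rng.random() < p_block:
                g.add_edge(i, j)
    return g, set(block)


class TestMcode:
    def test_k5_with_pendant_path(self):
        mods = mcode_modules(k5_plus_pendant())
        assert mods[0].nodes == ("k0", "k1", "k2", "k3", "k4")
        assert mods[0].score == pytest.approx(5.0)

    def test_edgeless_graph(self):
        g = nx.empty_graph(6)
        assert mcode_modules(g) == []

    def test_planted_dense_block_recovered_every_seed(self):
        for seed in range(5):
            g, block = planted_block_graph(seed)
            mods = mcode_modules(g)
            assert mods, f"no module found for seed {seed}"
            top = set(int(v) for v in mods[0].nodes)
            assert len(top & block) >= 6

    def test_deterministic_across_runs(self):
        g, _ = planted_block_graph(1)
        assert mcode_modules(g) == mcode_modules(g)

    def test_isomorphism_equivariance(self):
        """Relabeling nodes relabels the modules. Ties between equal-weight
        nodes are broken lexicographically, so the exact-equality check uses
        an order-preserving relabeling; an order-scrambling one must still
        recover the same top module."""
        raw, _ = planted_block_graph(2)
        g = nx.relabel_nodes(raw, {v: f"v{v:03d}" for v in raw})
        keep_order = {v: f"w{v[1:]}" for v in g}  # preserves lexicographic order
        h = nx.relabel_nodes(g, keep_order)
        mods_g = mcode_modules(g)
        mods_h = mcode_modules(h)
        assert [m.nodes for m in mods_h] == [
            tuple(sorted(keep_order[v] for v in m.nodes)) for m in mods_g]
        assert [m.score for m in mods_h] == pytest.approx(
            [m.score for m in mods_g])
        scramble = {v: f"n{(int(v[1:]) * 37) % 97:03d}" for v in g}
        top = mcode_modules(nx.relabel_nodes(g, scramble))[0]
        assert set(top.nodes) == {scramble[v] for v in mods_g[0].nodes}

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_independent_reference(self, seed):
        g = nx.gnp_random_graph(10, 0.4, seed=seed)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g})
        ours = [(m.nodes, m.score) for m in mcode_modules(g)]
        ref = mcode_reference(g)
        assert [n for n, _ in ours] == [n for n, _ in ref]
        assert [s for _, s in ours] == pytest.approx([s for _, s in ref])

    def test_fluff_flagged_unimplemented(self):
        with pytest.raises(NotImplementedError):
            mcode_modules(k5_plus_pendant(), fluff=True)


class TestExtractEgo:
    def test_isolated_node(self):
        g = build_network(motif_df([("s1", "T1", "G1")]))
        g.add_node("lonely", role="site")
        ego = extract_ego(g, "lonely")
        assert list(ego.nodes) == ["lonely"]
        assert ego.number_of_edges() == 0

    def test_site_star(self):
        rows = [("s1", f"T{i}", f"G{i}") for i in range(7)]
        ego = extract_ego(build_network(motif_df(rows)), "s1")
        assert ego.number_of_nodes() == 8  # site + its 7 pair nodes

    def test_matches_bfs_oracle(self):
        g, _ = planted_block_graph(4)
        adjacency = {v: set(g.neighbors(v)) for v in g}
        for radius in (1, 2):
            ego = extract_ego(g, 0, radius=radius)
            assert set(ego.nodes) == ego_nodes_brute(adjacency, 0, radius)

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            extract_ego(nx.path_graph(3), "missing")
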