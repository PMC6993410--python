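"""Independent brute-force reference implementations.

Everything here works from definitions (sums, exhaustive scans, exact
rational arithmetic) and deliberately shares no code with the package, so
the package's statistics can be checked against them.
"""
from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import t as t_dist


def pearson_brute(x, y) -> float:
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def t_two_sample_brute(a, b) -> tuple[float, float, float]:
    """Pooled-variance t statistic, two-sided p, df — textbook formulas."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ssa = sum((v - ma) ** 2 for v in a)
    ssb = sum((v - mb) ** 2 for v in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), df)
    return t, p, df


def bh_brute(p) -> list[float]:
    """Step-up adjustment by exhaustive min-over-j>=i scan."""
    p = [float(v) for v in p]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank, i in enumerate(order, start=1):
        candidates = []
        for rank2, j in enumerate(order, start=1):
            if rank2 >= rank:
                candidates.append(p[j] * m / rank2)
        adj[i] = min(1.0, min(candidates))
    return adj


def fisher_greater_brute(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p by exact hypergeometric tail.

    Table [[a, b], [c, d]]: P(X >= a) where X ~ Hypergeom(N=a+b+c+d,
    K=a+c, n=a+b), computed in exact rational arithmetic.
    """
    n_total = a + b + c + d
    k_col = a + c
    n_row = a + b
    denom = math.comb(n_total, n_row)
    total = Fraction(0)
    for x in range(a, min(k_col, n_row) + 1):
        if n_row - x > n_total - k_col:
            continue
        total += Fraction(math.comb(k_col, x) * math.comb(n_total - k_col,
                                                          n_row - x), denom)
    return float(total)


def degrees_brute(edges, nodes) -> dict:
    deg = {n: 0 for n in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    return deg


def ego_nodes_brute(adjacency: dict, start, radius: int) -> set:
    """Plain BFS to the given depth."""
    frontier = {start}
    seen = {start}
    for _ in range(radius):
        nxt = set()
        for v in frontier:
            for w in adjacency.get(v, ()):
                if w not in seen:
                    nxt.add(w)
        seen |= nxt
        frontier = nxt
    return seen


def exact_r_pair(r: float, n: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors whose sample Pearson correlation is exactly ``r``
    (up to float rounding): built from orthogonal centered directions."""
    u = np.zeros(n)
    u[0], u[1] = 1.0, -1.0
    w = np.ones(n)
    w[: n // 2] = -1.0
    w -= w.mean()
    u /= np.linalg.norm(u)
    w /= np.linalg.norm(w)
    x = u
    y = r * u + math.sqrt(1 - r * r) * w
    return x, y
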