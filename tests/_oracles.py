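"""Independent brute-force oracles used across the test suite.

These deliberately re-derive every quantity from first principles —
exhaustive shortest-path enumeration, dense eigendecomposition, explicit
induced subgraphs, subset enumeration, step-up recursion — and never call
into the code paths they are checking.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def oracle_centralities(g: nx.Graph) -> dict[str, dict]:
    """All six screening centralities by exhaustive/dense computation."""
    nodes = list(g.nodes)
    n = len(nodes)

    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        sigma = len(paths)
        for v in nodes:
            if v not in (s, t):
                bc[v] += sum(1 for p in paths if v in p) / sigma

    cc = {}
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        tot = sum(lengths.values())
        s_comp = len(lengths)
        cc[v] = 0.0 if tot == 0 or n <= 1 else (s_comp - 1) ** 2 / ((n - 1) * tot)

    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    w, vecs = np.linalg.eigh(a)
    vec = np.abs(vecs[:, int(np.argmax(w))])
    if vec.max() > 0:
        vec = vec / vec.max()
    ec = dict(zip(nodes, vec))

    dc = {v: g.degree(v) for v in nodes}

    lac = {}
    for v in nodes:
        nbrs = list(g[v])
        if not nbrs:
            lac[v] = 0.0
            continue
        h = g.subgraph(nbrs)
        lac[v] = sum(d for _, d in h.degree) / len(nbrs)

    nc = {}
    for v in nodes:
        total = 0.0
        for u in g[v]:
            z = len(set(g[v]) & set(g[u]))  # triangles on edge (v, u)
            denom = min(g.degree(v) - 1, g.degree(u) - 1)
            if denom > 0:
                total += z / denom
        nc[v] = total
    return {"dc": dc, "bc": bc, "cc": cc, "ec": ec, "lac": lac, "nc": nc}


def oracle_hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by summing the exact pmf with integer binomials."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


def oracle_hypergeom_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element universe."""
    universe = range(N)
    marked = set(range(K))  # which K elements carry the annotation
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return hits / total


def oracle_bh(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written directly from the definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, pvalues[i] * m / (rank_from_top + 1))
        q[i] = min(1.0, running_min)
    return q


def oracle_logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Log-rank O/E/V accumulation written independently, plus chi2 p-value."""
    from scipy.stats import chi2 as chi2_dist

    pooled = [(t, e, 0) for t, e in zip(times_a, events_a)]
    pooled += [(t, e, 1) for t, e in zip(times_b, events_b)]
    event_times = sorted({t for t, e, _ in pooled if e == 1})
    o = ex = var = 0.0
    for ti in event_times:
        at_risk = [(t, e, grp) for t, e, grp in pooled if t >= ti]
        n = len(at_risk)
        n_a = sum(1 for t, e, grp in at_risk if grp == 0)
        d = sum(1 for t, e, _ in pooled if t == ti and e == 1)
        d_a = sum(1 for t, e, grp in pooled if t == ti and e == 1 and grp == 0)
        o += d_a
        ex += d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (o - ex) ** 2 / var
    return chi2, float(chi2_dist.sf(chi2, 1))


def random_connected_graph(rng: np.random.Generator, n_max: int = 12, n_min: int = 3) -> nx.Graph:
    """A connected G(n, p) graph with string node labels."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.25, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if n == 1 or nx.is_connected(g):
            return nx.relabel_nodes(g, {v: f"N{v}" for v in g.nodes})
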