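"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: set partitions are
enumerated recursively, shortest distances come from exhaustive simple-path
enumeration, and hypergeometric tails are summed from binomial coefficients.
"""

from __future__ import annotations

from math import comb

import networkx as nx


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [subset + [first]] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_shortest_distance(g: nx.Graph, u, v) -> float | None:
    """Minimum total weight over every simple path from u to v."""
    best = None
    for path in nx.all_simple_paths(g, u, v):
        d = sum(g[a][b].get("weight", 1.0) for a, b in zip(path, path[1:]))
        if best is None or d < best:
            best = d
    return best


def brute_retained_paths(g: nx.Graph, sources, sinks, max_nodes: int = 3):
    """All simple paths with <= max_nodes nodes whose length equals the true
    shortest distance between their endpoints."""
    retained = set()
    for u in sources:
        for t in sinks:
            if u == t or not nx.has_path(g, u, t):
                continue
            d_true = brute_shortest_distance(g, u, t)
            for path in nx.all_simple_paths(g, u, t, cutoff=max_nodes - 1):
                d = sum(g[a][b].get("weight", 1.0) for a, b in zip(path, path[1:]))
                if abs(d - d_true) <= 1e-12 * max(1.0, abs(d_true)):
                    retained.add((tuple(path), round(d, 12)))
    return retained


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for a hypergeometric by direct combinatorial summation."""
    total = comb(N, n)
    num = sum(comb(K, i) * comb(N - K, n - i)
              for i in range(k, min(K, n) + 1) if n - i <= N - K)
    return num / total


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        j = m - rank_from_end  # 1-based rank of this p-value
        running = min(running, m * pvals[idx] / j)
        adj[idx] = running
    return adj


def random_connected_graph(rng, n: int, p: float) -> nx.Graph:
    """Seeded Erdos-Renyi graph, resampled until connected, unit weights."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if g.number_of_edges() > 0 and nx.is_connected(g):
            nx.set_edge_attributes(g, 1.0, "weight")
            return g
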