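"""Two-level map-equation community detection on interaction graphs.

The map equation scores a partition of a graph by the expected per-step
description length L of an unbiased random walk encoded with a two-level
codebook: an index codebook announcing community entries and one codebook
per community for within-community moves and exits. For an undirected
graph the stationary visit frequency of node a is

    p_a = strength(a) / (2 W),

the community exit/enter rate is the relative cut weight, and

    L = q * H(Q) + sum_x (p_x + q_x) * H(P_x)

where q = sum_x q_x is the total enter rate, H(Q) the entropy of the
normalized enter rates, and H(P_x) the entropy of the community codebook
(exit codeword plus member visit rates). Minimizing L over partitions
recovers the community structure best compressing the walk.

The minimizer is a seeded greedy search: repeated sweeps move each node to
the adjacent community that lowers L most, communities are then aggregated
into supernodes and the sweeps repeat, with the best of ``n_restarts``
shuffled restarts returned. All logarithms are base 2; 0*log(0) is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .enrich import hypergeom_enrich
from .data_io import GeneSetCollection
from .network import CTPGraph

logger = logging.getLogger(__name__)

MOVE_TOL = 1e-10


def _plogp(x: float) -> float:
    return x * np.log2(x) if x > 0 else 0.0


def _entropy(probs) -> float:
    return float(-sum(_plogp(p) for p in probs))


def visit_frequencies(g: nx.Graph) -> dict:
    """Stationary visit distribution of the unbiased walk: strength / 2W.

    On a disconnected graph the largest connected component is analyzed,
    with a warning.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("visit_frequencies: empty graph")
    if not nx.is_connected(g):
        cc = max(nx.connected_components(g), key=len)
        logger.warning("visit_frequencies: graph disconnected; using largest component "
                       "(%d of %d nodes)", len(cc), g.number_of_nodes())
        g = g.subgraph(cc)
    strength = {n: sum(d.get("weight", 1.0) for _, _, d in g.edges(n, data=True)) for n in g}
    two_w = sum(strength.values())
    if two_w == 0:
        raise ValueError("visit_frequencies: graph has no edges")
    return {n: s / two_w for n, s in strength.items()}


@dataclass
class MapEquationTerms:
    """Full decomposition of the two-level map equation for one partition."""

    codelength: float                 # L, bits per step
    index_rate: float                 # total community enter rate
    index_entropy: float              # H over normalized enter rates
    enter_rates: list[float]          # per community (equals exit for undirected)
    exit_rates: list[float]
    codebook_rates: list[float]       # p_x + q_x per community
    codebook_entropies: list[float]   # module codebook entropy per community

    @property
    def n_communities(self) -> int:
        return len(self.enter_rates)


def map_equation(g: nx.Graph, partition: dict) -> MapEquationTerms:
    """Evaluate the map equation for a partition covering all nodes of g."""
    missing = set(g.nodes) - set(partition)
    if missing:
        raise ValueError(f"map_equation: partition does not cover nodes {sorted(missing)[:5]}")
    p = visit_frequencies_full(g)
    two_w = sum(2.0 * d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    labels = sorted({partition[n] for n in g.nodes})
    exit_rates, codebook_rates, codebook_entropies = [], [], []
    for x in labels:
        members = [n for n in g.nodes if partition[n] == x]
        p_x = sum(p[n] for n in members)
        cut = 0.0
        for n in members:
            for _, v, d in g.edges(n, data=True):
                if partition[v] != x:
                    cut += d.get("weight", 1.0)
        q_x = cut / two_w
        k_x = p_x + q_x
        probs = [q_x / k_x] + [p[n] / k_x for n in members] if k_x > 0 else []
        exit_rates.append(q_x)
        codebook_rates.append(k_x)
        codebook_entropies.append(_entropy(probs))
    q = sum(exit_rates)
    index_entropy = _entropy([qx / q for qx in exit_rates]) if q > 0 else 0.0
    L = q * index_entropy + sum(k * h for k, h in zip(codebook_rates, codebook_entropies))
    return MapEquationTerms(
        codelength=L,
        index_rate=q,
        index_entropy=index_entropy,
        enter_rates=list(exit_rates),
        exit_rates=exit_rates,
        codebook_rates=codebook_rates,
        codebook_entropies=codebook_entropies,
    )


def visit_frequencies_full(g: nx.Graph) -> dict:
    """strength/2W over the whole (possibly disconnected) graph, no warning."""
    strength = {n: sum(d.get("weight", 1.0) for _, _, d in g.edges(n, data=True)) for n in g}
    two_w = sum(strength.values())
    if two_w == 0:
        raise ValueError("graph has no edges")
    return {n: s / two_w for n, s in strength.items()}


# ---------------------------------------------------------------------------
# greedy minimizer
# ---------------------------------------------------------------------------


def _codelength_from_arrays(q_list, p_list, const_term) -> float:
    # L = plogp(q) - 2 sum plogp(q_x) + sum plogp(p_x + q_x) - sum_a plogp(p_a)
    q = sum(q_list)
    return (_plogp(q)
            - 2.0 * sum(_plogp(qx) for qx in q_list)
            + sum(_plogp(px + qx) for px, qx in zip(p_list, q_list))
            - const_term)


def _local_move(adj, p, part, p_x, cut_x, rng, tol):
    """One node-moving phase; mutates part/p_x/cut_x in place. Returns True if any move."""
    n = len(p)
    moved_any = False
    while True:
        changed = False
        for u in rng.permutation(n):
            c0 = part[u]
            w_to: dict[int, float] = {}
            str_u = 0.0
            for v, w in adj[u]:
                w_to[part[v]] = w_to.get(part[v], 0.0) + w
                str_u += w
            q_total = sum(cut_x.values())
            cut0, p0 = cut_x[c0], p_x[c0]
            cut0_new = cut0 - str_u + 2.0 * w_to.get(c0, 0.0)
            best_c, best_delta = c0, 0.0
            for c1 in w_to:
                if c1 == c0:
                    continue
                cut1, p1 = cut_x[c1], p_x[c1]
                cut1_new = cut1 + str_u - 2.0 * w_to.get(c1, 0.0)
                q_new = q_total + (cut0_new - cut0) + (cut1_new - cut1)
                old = (_plogp(q_total) - 2.0 * (_plogp(cut0) + _plogp(cut1))
                       + _plogp(p0 + cut0) + _plogp(p1 + cut1))
                new = (_plogp(q_new) - 2.0 * (_plogp(cut0_new) + _plogp(cut1_new))
                       + _plogp(p0 - p[u] + cut0_new) + _plogp(p1 + p[u] + cut1_new))
                delta = new - old
                if delta < best_delta - tol or (delta < best_delta + tol and
                                                best_c != c0 and c1 < best_c):
                    best_c, best_delta = c1, delta
            if best_c != c0 and best_delta < -tol:
                part[u] = best_c
                p_x[c0] -= p[u]
                p_x[best_c] += p[u]
                cut_x[c0] = cut0_new
                cut_x[best_c] = cut_x[best_c] + str_u - 2.0 * w_to.get(best_c, 0.0)
                changed = moved_any = True
        if not changed:
            break
    return moved_any


def _aggregate(adj, p, part):
    """Collapse communities into supernodes; intra-community weight is dropped
    (it does not enter L, which depends only on cuts and visit masses)."""
    labels = sorted(set(part))
    relabel = {c: i for i, c in enumerate(labels)}
    m = len(labels)
    p_new = [0.0] * m
    for u, pu in enumerate(p):
        p_new[relabel[part[u]]] += pu
    w_new: dict[tuple[int, int], float] = {}
    for u in range(len(p)):
        cu = relabel[part[u]]
        for v, w in adj[u]:
            if u < v:
                cv = relabel[part[v]]
                if cu != cv:
                    key = (min(cu, cv), max(cu, cv))
                    w_new[key] = w_new.get(key, 0.0) + w
    adj_new = [[] for _ in range(m)]
    for (a, b), w in w_new.items():
        adj_new[a].append((b, w))
        adj_new[b].append((a, w))
    mapping = [relabel[c] for c in part]
    return adj_new, p_new, mapping


def detect_communities(g: nx.Graph, seed: int, n_restarts: int = 10,
                       tol: float = MOVE_TOL) -> dict:
    """Greedy map-equation minimization, best of ``n_restarts`` seeded restarts.

    Disconnected input is reduced to its largest component with a warning.
    The returned labels are 0-based, contiguous, and canonicalized by first
    appearance in the graph's node order; the result is deterministic given
    (graph, seed, n_restarts).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("detect_communities: empty graph")
    if not nx.is_connected(g):
        cc = max(nx.connected_components(g), key=len)
        logger.warning("detect_communities: graph disconnected; using largest component "
                       "(%d of %d nodes)", len(cc), g.number_of_nodes())
        g = g.subgraph(cc).copy()
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 1:
        return {nodes[0]: 0}
    idx = {node: i for i, node in enumerate(nodes)}
    adj = [[] for _ in range(n)]
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        adj[idx[u]].append((idx[v], w))
        adj[idx[v]].append((idx[u], w))
    two_w = sum(w for a in adj for _, w in a)
    # work in relative units so cuts are rates directly
    adj = [[(v, w / two_w) for v, w in a] for a in adj]
    p = [sum(w for _, w in a) for a in adj]
    const_term = sum(_plogp(pa) for pa in p)

    def eval_assignment(assignment):
        labels = set(assignment)
        p_l = {c: 0.0 for c in labels}
        cut_l = {c: 0.0 for c in labels}
        for u in range(n):
            p_l[assignment[u]] += p[u]
            for v, w in adj[u]:
                if assignment[v] != assignment[u]:
                    cut_l[assignment[u]] += w
        return _codelength_from_arrays(list(cut_l.values()), list(p_l.values()), const_term)

    rng = np.random.default_rng(seed)
    best_assignment = [0] * n          # all-in-one as baseline candidate
    best_L = eval_assignment(best_assignment)
    singletons = list(range(n))
    L_single = eval_assignment(singletons)
    if L_single < best_L - tol:
        best_assignment, best_L = singletons, L_single

    for _ in range(max(1, n_restarts)):
        level_adj = [list(a) for a in adj]
        level_p = list(p)
        assignment = list(range(n))    # original node -> current-level node
        while True:
            m = len(level_p)
            part = list(range(m))
            p_x = {i: level_p[i] for i in range(m)}
            cut_x = {i: sum(w for _, w in level_adj[i]) for i in range(m)}
            moved = _local_move(level_adj, level_p, part, p_x, cut_x, rng, tol)
            if not moved or len(set(part)) == m:
                break
            level_adj, level_p, mapping = _aggregate(level_adj, level_p, part)
            assignment = [mapping[part[a]] for a in assignment]
            if len(level_p) == 1:
                break
        L = eval_assignment(assignment)
        if L < best_L - tol:
            best_assignment, best_L = assignment, L

    canonical: dict[int, int] = {}
    out: dict = {}
    for i, node in enumerate(nodes):
        c = best_assignment[i]
        if c not in canonical:
            canonical[c] = len(canonical)
        out[node] = canonical[c]
    return out


# ---------------------------------------------------------------------------
# coverage metrics
# ---------------------------------------------------------------------------


def reported_communities(partition: dict, min_size: int = 3) -> frozenset:
    """Community labels with at least ``min_size`` members."""
    sizes: dict = {}
    for c in partition.values():
        sizes[c] = sizes.get(c, 0) + 1
    return frozenset(c for c, s in sizes.items() if s >= min_size)


def community_component_coverage(partition: dict, ctp: CTPGraph,
                                 min_size: int = 3) -> dict[str, float]:
    """Per herb, the fraction of retained components with at least one target
    inside a reported community (size >= ``min_size``)."""
    reported = reported_communities(partition, min_size)
    coverage: dict[str, float] = {}
    for herb, comps in sorted(ctp.herb_components.items()):
        if not comps:
            logger.warning("coverage: herb %s has no components, excluded", herb)
            continue
        covered = 0
        for comp in comps:
            targets = ctp.component_targets(comp)
            if any(partition.get(t) in reported for t in targets):
                covered += 1
        coverage[herb] = covered / len(comps)
    return coverage


def community_pathway_similarity(community_genes: set, network_genes: set,
                                 sets: GeneSetCollection, alpha: float = 0.05,
                                 background: set | None = None,
                                 use_fdr: bool = False) -> float:
    """Fraction of the pathways enriched in the full network's genes that are
    also enriched in the community genes (hypergeometric p < alpha)."""
    if not community_genes or not network_genes:
        raise ValueError("community_pathway_similarity: empty gene set")
    def enriched(genes):
        results = hypergeom_enrich(genes, sets, background=background)
        key = (lambda r: r.q) if use_fdr else (lambda r: r.p)
        return {r.pathway for r in results if key(r) < alpha}
    network_hits = enriched(network_genes)
    if not network_hits:
        raise ValueError("community_pathway_similarity: no pathway enriched in the network genes")
    community_hits = enriched(community_genes)
    return len(network_hits & community_hits) / len(network_hits)
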