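import networkx as nx
import numpy as np
import pytest

from formularank import (build_ct, community_component_coverage,
                         community_pathway_similarity, detect_communities,
                         map_equation, merge_ctp, reported_communities,
                         visit_frequencies)
from formularank.data_io import ComponentRecord, GeneSet, GeneSetCollection

from oracles import random_connected_graph, set_partitions


def weighted_graph(*edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


class TestVisitFrequencies:
    def test_regular_graph_is_uniform(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, 1.0, "weight")
        p = visit_frequencies(g)
        assert all(v == pytest.approx(1 / 3) for v in p.values())

    def test_path_graph_degrees_over_2m(self):
        g = weighted_graph(("A", "B", 1.0), ("B", "C", 1.0))
        assert visit_frequencies(g) == {"A": 0.25, "B": 0.5, "C": 0.25}

    def test_weighted_path_strength_over_2w(self):
        g = weighted_graph(("A", "B", 1.0), ("B", "C", 3.0))
        p = visit_frequencies(g)
        assert p == {"A": 0.125, "B": 0.5, "C": 0.375}

    def test_sums_to_one(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(rng, 15, 0.3)
        assert sum(visit_frequencies(g).values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            visit_frequencies(nx.Graph())


def codelength_identity_gap(terms):
    """Residual of L = q*H(Q) + sum_x k_x*H(k_x), recomputed from the parts."""
    recomputed = (terms.index_rate * terms.index_entropy
                  + sum(k * h for k, h in zip(terms.codebook_rates,
                                              terms.codebook_entropies)))
    return abs(terms.codelength - recomputed)


class TestMapEquation:
    def test_two_node_one_community_is_one_bit(self, two_node_graph):
        terms = map_equation(two_node_graph, {"a": 0, "b": 0})
        assert terms.codelength == pytest.approx(1.0, abs=1e-12)
        assert terms.index_rate == 0.0

    def test_two_node_singletons_is_three_bits(self, two_node_graph):
        terms = map_equation(two_node_graph, {"a": 0, "b": 1})
        assert terms.codelength == pytest.approx(3.0, abs=1e-12)

    def test_single_community_equals_visit_entropy(self):
        rng = np.random.default_rng(3)
        g = random_connected_graph(rng, 10, 0.4)
        p = visit_frequencies(g)
        entropy = -sum(v * np.log2(v) for v in p.values())
        terms = map_equation(g, {n: 0 for n in g})
        assert terms.codelength == pytest.approx(entropy, abs=1e-12)
        assert terms.index_rate == 0.0

    def test_partial_partition_rejected(self, two_node_graph):
        with pytest.raises(ValueError, match="cover"):
            map_equation(two_node_graph, {"a": 0})

    @pytest.mark.parametrize("seed", range(5))
    def test_identity_holds_on_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, 12, 0.3)
        part = {n: int(rng.integers(3)) for n in g}
        terms = map_equation(g, part)
        assert codelength_identity_gap(terms) < 1e-12

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(9)
        g = random_connected_graph(rng, 10, 0.4)
        part = {n: n % 3 for n in g}
        relabeled = {n: (part[n] + 5) * 7 for n in g}  # permuted community ids
        assert map_equation(g, part).codelength == pytest.approx(
            map_equation(g, relabeled).codelength, abs=1e-12)
        g2 = nx.relabel_nodes(g, {n: f"x{n}" for n in g})
        part2 = {f"x{n}": part[n] for n in g}
        assert map_equation(g2, part2).codelength == pytest.approx(
            map_equation(g, part).codelength, abs=1e-12)


class TestDetectCommunities:
    def test_two_node_graph_merges(self, two_node_graph):
        assert detect_communities(two_node_graph, seed=0) == {"a": 0, "b": 0}

    def test_two_cliques_recovered_exactly(self, two_clique_graph):
        part = detect_communities(two_clique_graph, seed=1)
        assert len(set(part.values())) == 2
        assert len({part[n] for n in range(6)}) == 1
        assert len({part[n] for n in range(6, 12)}) == 1

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "weight")
        assert set(detect_communities(g, seed=0).values()) == {0}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_minimum_on_small_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(4, 9))
        g = random_connected_graph(rng, n, 0.5)
        best = min(
            map_equation(g, {x: i for i, sub in enumerate(pp) for x in sub}).codelength
            for pp in set_partitions(list(g.nodes))
        )
        part = detect_communities(g, seed=seed, n_restarts=10)
        L = map_equation(g, part).codelength
        assert L == pytest.approx(best, abs=1e-10)
        assert codelength_identity_gap(map_equation(g, part)) < 1e-12

    def test_never_worse_than_trivial_partitions(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            g = random_connected_graph(rng, 12, 0.25)
            L = map_equation(g, detect_communities(g, seed=5)).codelength
            L_one = map_equation(g, {n: 0 for n in g}).codelength
            L_single = map_equation(g, {n: i for i, n in enumerate(g)}).codelength
            assert L <= min(L_one, L_single) + 1e-10

    def test_deterministic_given_seed(self, two_clique_graph):
        a = detect_communities(two_clique_graph, seed=7)
        b = detect_communities(two_clique_graph, seed=7)
        assert a == b

    def test_disconnected_uses_largest_component(self):
        g = weighted_graph(("a", "b", 1.0), ("b", "c", 1.0), ("x", "y", 1.0))
        part = detect_communities(g, seed=0)
        assert set(part) == {"a", "b", "c"}


class TestCoverage:
    def _ctp(self, herb_map, ppi_edges=()):
        records = [ComponentRecord(record_id=c, name=c, herb=h, ob=50, dl=0.5)
                   for h, comps in herb_map.items() for c in comps]
        target_map = {c: frozenset({f"T_{c.upper()}"}) for h in herb_map for c in herb_map[h]}
        ct = build_ct(records, target_map)
        ppi = nx.Graph()
        for u, v in ppi_edges:
            ppi.add_edge(u, v, weight=1.0)
        nx.set_node_attributes(ppi, "protein", "kind")
        return merge_ctp(ct, ppi)

    def test_full_coverage(self):
        ctp = self._ctp({"H1": ["a", "b"]})
        part = {n: 0 for n in ctp.graph}
        assert community_component_coverage(part, ctp, min_size=3) == {"H1": 1.0}

    def test_three_of_four_covered(self):
        ctp = self._ctp({"H1": ["a", "b", "c", "d"]})
        part = {n: 0 for n in ctp.graph}
        part["T_D"] = 99  # orphan d's only target into an unreported singleton
        assert community_component_coverage(part, ctp, min_size=3)["H1"] == 0.75

    def test_min_size_threshold_hides_small_communities(self):
        ctp = self._ctp({"H1": ["a"]})
        part = {n: 0 for n in ctp.graph}
        assert community_component_coverage(part, ctp, min_size=99)["H1"] == 0.0

    def test_reported_communities_sizes(self):
        part = {1: 0, 2: 0, 3: 0, 4: 1, 5: 1}
        assert reported_communities(part, min_size=3) == {0}
        assert reported_communities(part, min_size=2) == {0, 1}


class TestPathwaySimilarity:
    def _sets(self):
        coll = GeneSetCollection()
        # 4 enrichable pathways plus background filler
        for i, genes in enumerate([{"A1", "A2", "A3"}, {"B1", "B2", "B3"},
                                   {"C1", "C2", "C3"}, {"D1", "D2", "D3"}]):
            coll.sets[f"PW{i}"] = GeneSet(f"PW{i}", "", frozenset(genes))
        filler = frozenset(f"Z{j}" for j in range(40))
        coll.sets["BG"] = GeneSet("BG", "", filler)
        return coll

    def test_identity_gives_one(self):
        coll = self._sets()
        genes = {"A1", "A2", "A3", "B1", "B2", "B3"}
        assert community_pathway_similarity(genes, genes, coll) == 1.0

    def test_disjoint_communities_give_zero(self):
        coll = self._sets()
        network = {"A1", "A2", "A3"}
        community = {"Z1"}
        assert community_pathway_similarity(community, network, coll) == 0.0

    def test_dropping_one_of_four_pathways_gives_three_quarters(self):
        coll = self._sets()
        network = {"A1", "A2", "A3", "B1", "B2", "B3", "C1", "C2", "C3", "D1", "D2", "D3"}
        community = network - {"D1", "D2", "D3"}
        assert community_pathway_similarity(community, network, coll) == 0.75

    def test_no_network_enrichment_is_error(self):
        coll = self._sets()
        with pytest.raises(ValueError, match="no pathway"):
            community_pathway_similarity({"Z1"}, {"Z1", "Z2"}, coll)
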