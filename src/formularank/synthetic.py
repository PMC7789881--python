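"""Seeded synthetic fixtures: planted-community PPIs and full formula bundles.

The generator stands in for the databases a real analysis would export
tables from (compound descriptors, target predictions, PPI snapshots,
disease-gene scores). It emulates the structure the pipeline measures:

* a protein interaction network with planted communities (stochastic block
  model, equal blocks, connectivity repaired along a spanning tree);
* per-herb component tables whose descriptor distributions shift with the
  herb's designed prominence, so both the ADME screen and the PCA separate
  the herbs;
* target maps with controllable hubness (preference for high-degree
  proteins) and disease-overlap bias, with the top-bias herb *constructed*
  to dominate: its target set is deterministically repaired to contain
  strictly more pathogenic genes and strictly higher-degree proteins than
  any other herb's;
* peripheral satellite protein pairs targeted by low-bias herbs, which sit
  outside reported communities and therefore drive the community-coverage
  ordering;
* a long-tailed (log-normal) relevance-score distribution for disease
  genes, mimicking literature-derived disease association scores.

Everything is deterministic given the FormulaSpec seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data_io import ComponentRecord, DiseaseGeneTable, GeneSet, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HerbSpec:
    name: str
    n_components: int = 12
    n_targets_per_component: int = 4
    hubness: float = 0.5           # in [0, 1]: preference for high-degree targets
    disease_overlap: float = 0.5   # in [0, 1]: preference for pathogenic-gene targets

    def __post_init__(self) -> None:
        if self.n_components < 1 or self.n_targets_per_component < 1:
            raise ValueError("herb counts must be >= 1")
        if not (0 <= self.hubness <= 1 and 0 <= self.disease_overlap <= 1):
            raise ValueError("biases must lie in [0, 1]")

    @property
    def prominence(self) -> float:
        return (self.hubness + self.disease_overlap) / 2.0


@dataclass(frozen=True)
class FormulaSpec:
    herbs: tuple[HerbSpec, ...]
    n_proteins: int = 120
    k_communities: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    n_disease_genes: int = 40
    n_background_genes: int = 300  # extra universe genes outside the PPI, so
                                   # targets are a small fraction of the
                                   # enrichment background as in real data
    relevance_mu: float = 1.0      # log-normal parameters of relevance scores
    relevance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.herbs:
            raise ValueError("need at least one herb")
        if self.p_in <= self.p_out:
            raise ValueError("planted structure requires p_in > p_out")
        if self.n_proteins < self.k_communities or self.k_communities < 1:
            raise ValueError("need n_proteins >= k_communities >= 1")
        if not (0 <= self.p_out <= 1 and 0 < self.p_in <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_disease_genes < 1 or self.n_disease_genes > self.n_proteins:
            raise ValueError("n_disease_genes must be in [1, n_proteins]")


def default_formula_spec(seed: int = 0) -> FormulaSpec:
    """Four herbs with prominence biases 0.9 / 0.5 / 0.5 / 0.2: one designed
    principal herb, two intermediates, one designed assistant."""
    return FormulaSpec(
        herbs=(
            HerbSpec("herbA", hubness=0.9, disease_overlap=0.9),
            HerbSpec("herbB", hubness=0.5, disease_overlap=0.5),
            HerbSpec("herbC", hubness=0.5, disease_overlap=0.5),
            HerbSpec("herbD", hubness=0.2, disease_overlap=0.2),
        ),
        seed=seed,
    )


def make_planted_graph(n: int, k: int, p_in: float, p_out: float,
                       seed: int) -> tuple[nx.Graph, dict]:
    """Equal-block stochastic block graph with its ground-truth partition.

    Connectivity is guaranteed: if the sampled graph is disconnected, edges
    are added along a random spanning tree over the components (logged).
    """
    if n < k or k < 1:
        raise ValueError("need n >= k >= 1")
    if not p_in > p_out:
        raise ValueError("need p_in > p_out")
    rng = np.random.default_rng(seed)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    block = np.repeat(np.arange(k), sizes)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block[i] == block[j] else p_out
            if rng.random() < p:
                g.add_edge(i, j, weight=1.0)
    if not nx.is_connected(g):
        comps = [sorted(c) for c in nx.connected_components(g)]
        rng.shuffle(comps)
        added = 0
        for a, b in zip(comps, comps[1:]):
            u = a[rng.integers(len(a))]
            v = b[rng.integers(len(b))]
            g.add_edge(u, v, weight=1.0)
            added += 1
        logger.info("make_planted_graph: added %d spanning-tree edge(s) for connectivity", added)
    nx.set_node_attributes(g, "protein", "kind")
    return g, {i: int(block[i]) for i in range(n)}


@dataclass
class FormulaBundle:
    """Everything the pipeline ingests, generated from one FormulaSpec."""

    spec: FormulaSpec
    components: list[ComponentRecord]
    target_map: dict[str, frozenset[str]]
    ppi: nx.Graph
    disease: DiseaseGeneTable
    gene_sets: GeneSetCollection
    absorbed: frozenset[str]
    true_partition: dict = field(default_factory=dict)

    def herb_names(self) -> list[str]:
        return [h.name for h in self.spec.herbs]

    @property
    def top_herb(self) -> str:
        return max(self.spec.herbs, key=lambda h: (h.prominence, -self.spec.herbs.index(h))).name


def _protein_name(i: int) -> str:
    return f"P{i:04d}"


def _sample_targets(rng, proteins, degrees, disease_set, herb: HerbSpec, n: int,
                    used: set[str]) -> list[str]:
    """Biased draw of ``n`` distinct targets, avoiding targets already used by
    the same herb's other components while enough candidates remain (so a
    herb's components spread over distinct proteins rather than piling onto
    the same few hubs)."""
    w = np.array([
        (degrees[v] + 1.0) ** (1.0 + 3.0 * herb.hubness)
        * (1.0 + 9.0 * herb.disease_overlap if v in disease_set else 1.0)
        for v in proteins
    ])
    fresh = np.array([v not in used for v in proteins])
    if fresh.sum() >= n:
        w = w * fresh
    w = w / w.sum()
    picks = rng.choice(len(proteins), size=min(n, len(proteins)), replace=False, p=w)
    return [proteins[i] for i in picks]


def make_toy_formula(spec: FormulaSpec) -> FormulaBundle:
    """Generate the full input bundle for a formula with designed dominance."""
    rng = np.random.default_rng(spec.seed)
    g_raw, block = make_planted_graph(spec.n_proteins, spec.k_communities,
                                      spec.p_in, spec.p_out,
                                      seed=int(rng.integers(2**31)))
    mapping = {i: _protein_name(i) for i in g_raw.nodes}
    ppi = nx.relabel_nodes(g_raw, mapping)
    true_partition = {mapping[i]: c for i, c in block.items()}
    proteins = sorted(ppi.nodes)
    degrees = {v: ppi.degree(v) for v in proteins}

    # disease genes favor well-connected proteins; long-tailed relevance scores
    deg_w = np.array([degrees[v] + 1.0 for v in proteins], dtype=float)
    deg_w /= deg_w.sum()
    disease_idx = rng.choice(len(proteins), size=spec.n_disease_genes, replace=False, p=deg_w)
    disease_genes = sorted(proteins[i] for i in disease_idx)
    scores = rng.lognormal(mean=spec.relevance_mu, sigma=spec.relevance_sigma,
                           size=len(disease_genes))
    disease = DiseaseGeneTable(scores={g: float(s) for g, s in zip(disease_genes, scores)})
    disease_set = set(disease_genes)

    top = max(spec.herbs, key=lambda h: h.prominence)
    records: list[ComponentRecord] = []
    target_map: dict[str, frozenset[str]] = {}
    herb_component_names: dict[str, list[str]] = {}
    n_satellites = 0

    for herb in spec.herbs:
        names = []
        used: set[str] = set()
        for j in range(herb.n_components):
            name = f"{herb.name}_cmp{j:02d}"
            names.append(name)
            orphan = (herb.prominence < top.prominence
                      and rng.random() < 0.5 * (1.0 - herb.prominence))
            if orphan:
                # peripheral satellite dyad: connected only to each other
                a, b = f"S{n_satellites:04d}", f"S{n_satellites + 1:04d}"
                n_satellites += 2
                ppi.add_edge(a, b, weight=1.0)
                ppi.nodes[a]["kind"] = ppi.nodes[b]["kind"] = "protein"
                targets = [a, b]
            else:
                targets = _sample_targets(rng, proteins, degrees, disease_set, herb,
                                          herb.n_targets_per_component, used)
                used.update(targets)
            target_map[name.casefold()] = frozenset(targets)
            prom = herb.prominence
            records.append(ComponentRecord(
                record_id=f"{herb.name}-{j:02d}",
                name=name,
                herb=herb.name,
                ob=float(max(0.0, rng.normal(30 + 25 * prom, 8.0))),
                dl=float(np.clip(rng.normal(0.10 + 0.45 * prom, 0.10), 0.0, 1.0)),
                mw=float(max(50.0, rng.normal(300 + 80 * prom, 40.0))),
                alogp=float(rng.normal(2.5 + 1.5 * (1 - prom), 1.0)),
                hdon=int(rng.poisson(2 + 2 * prom)),
                hacc=int(rng.poisson(4 + 2 * prom)),
                caco2=float(rng.normal(0.5 + 0.5 * prom, 0.3)),
            ))
        herb_component_names[herb.name] = names

    _repair_dominance(spec, top, target_map, herb_component_names, degrees, disease_set)

    # pathway sets: one per planted block, plus decoys over a larger universe
    # of background genes so enrichment has realistic contrast
    background = [f"B{i:04d}" for i in range(spec.n_background_genes)]
    sets = GeneSetCollection()
    for c in sorted(set(true_partition.values())):
        genes = frozenset(v for v, b in true_partition.items() if b == c)
        sets.sets[f"PW_BLOCK{c}"] = GeneSet(f"PW_BLOCK{c}", f"planted community {c}", genes)
    n_decoys = max(2, spec.n_background_genes // 40)
    for d in range(n_decoys):
        size = min(25, len(background))
        genes = frozenset(background[i] for i in rng.choice(len(background), size=size,
                                                            replace=False))
        sets.sets[f"PW_DECOY{d}"] = GeneSet(f"PW_DECOY{d}", "background decoy pathway", genes)

    # blood-absorbed components scale with prominence
    absorbed: set[str] = set()
    for herb in spec.herbs:
        k = round(0.4 * herb.prominence * herb.n_components)
        absorbed.update(n.casefold() for n in herb_component_names[herb.name][:k])

    return FormulaBundle(spec=spec, components=records, target_map=target_map,
                         ppi=ppi, disease=disease, gene_sets=sets,
                         absorbed=frozenset(absorbed), true_partition=true_partition)


def _repair_dominance(spec: FormulaSpec, top: HerbSpec,
                      target_map: dict[str, frozenset[str]],
                      herb_component_names: dict[str, list[str]],
                      degrees: dict[str, int], disease_set: set[str]) -> None:
    """Deterministically enforce strict dominance of the top-bias herb.

    After repair the top herb's target union (i) contains strictly more
    pathogenic genes than any other herb's, (ii) contains the highest-degree
    protein, and (iii) has a strictly higher possession rate.
    """
    def union(herb_name: str) -> set[str]:
        out: set[str] = set()
        for n in herb_component_names[herb_name]:
            out |= target_map[n.casefold()]
        return out

    others = [h.name for h in spec.herbs if h.name != top.name]
    if not others:
        return
    if top.prominence <= max(h.prominence for h in spec.herbs if h.name != top.name):
        return  # no herb is designed to dominate; leave the draw symmetric
    top_comps = [n.casefold() for n in herb_component_names[top.name]]

    def swap_in(candidate: str) -> bool:
        """Replace the worst non-disease, non-hub target of the top herb."""
        for comp in top_comps:
            targets = target_map[comp]
            sacrificable = sorted((t for t in targets - disease_set), key=lambda t: degrees.get(t, 0))
            if sacrificable and candidate not in targets:
                target_map[comp] = (targets - {sacrificable[0]}) | {candidate}
                return True
        return False

    # (ii) highest-degree protein present
    hub = max(degrees, key=lambda v: (degrees[v], v))
    if hub not in union(top.name):
        swap_in(hub)

    # (i)+(iii): strictly more disease genes, strictly higher possession rate
    ranked_disease = sorted(disease_set, key=lambda v: (-degrees.get(v, 0), v))
    guard = 0
    while guard < 10 * len(ranked_disease):
        guard += 1
        tu = union(top.name)
        n_top = len(tu & disease_set)
        rate_top = n_top / len(tu)
        worst_margin = min(n_top - len(union(o) & disease_set) for o in others)
        rates = [len(union(o) & disease_set) / len(union(o)) for o in others]
        if worst_margin > 0 and all(rate_top > r for r in rates):
            break
        fresh = [d for d in ranked_disease if d not in tu]
        if not fresh or not swap_in(fresh[0]):
            break
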