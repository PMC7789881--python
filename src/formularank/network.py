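"""Component-target (C-T) and merged component-target-protein (C-T-P) networks.

The C-T graph is bipartite: component nodes (case-folded names, node kind
``component``) connected to the protein targets they are predicted to hit
(uppercased symbols, kind ``protein``). Merging with a PPI edge list gives
the C-T-P graph on which degree, community and propagation statistics are
computed. A herb index records, per herb, the retained components and the
union of their targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .data_io import ComponentRecord

logger = logging.getLogger(__name__)


@dataclass
class CTGraph:
    """Bipartite component-target graph plus the herb index and unmapped report."""

    graph: nx.Graph
    herb_components: dict[str, frozenset[str]]   # herb -> retained component names (normalized)
    herb_targets: dict[str, frozenset[str]]      # herb -> protein symbols targeted
    unmapped: dict[str, list[str]] = field(default_factory=dict)  # herb -> components without targets


@dataclass
class CTPGraph:
    """Merged C-T-P graph with the herb index carried over from the C-T stage."""

    graph: nx.Graph
    herb_components: dict[str, frozenset[str]]
    herb_targets: dict[str, frozenset[str]]

    def protein_subgraph(self) -> nx.Graph:
        keep = [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "protein"]
        return self.graph.subgraph(keep).copy()

    def component_targets(self, component: str) -> frozenset[str]:
        if component not in self.graph:
            return frozenset()
        return frozenset(
            n for n in self.graph.neighbors(component)
            if self.graph.nodes[n].get("kind") == "protein"
        )


def build_ct(records: list[ComponentRecord],
             target_map: Mapping[str, frozenset[str]]) -> CTGraph:
    """Assemble the bipartite C-T graph from retained components and a target map.

    Components sharing a (normalized) name collapse to a single node; the
    herb index lists every herb contributing the component. Components
    absent from the target map are excluded from the graph and reported.
    """
    g = nx.Graph()
    herb_components: dict[str, set[str]] = {}
    herb_targets: dict[str, set[str]] = {}
    unmapped: dict[str, list[str]] = {}
    mappable = 0
    for r in records:
        name = r.norm_name
        herb_components.setdefault(r.herb, set()).add(name)
        targets = target_map.get(name)
        if not targets:
            unmapped.setdefault(r.herb, []).append(name)
            continue
        mappable += 1
        g.add_node(name, kind="component")
        for t in targets:
            g.add_node(t, kind="protein")
            g.add_edge(name, t, weight=1.0)
        herb_targets.setdefault(r.herb, set()).update(targets)
    if mappable == 0:
        raise ValueError("build_ct: no component maps to any target (empty network)")
    if unmapped:
        logger.info("build_ct: %d herb(s) have unmapped components: %s",
                    len(unmapped), {h: len(v) for h, v in unmapped.items()})
    return CTGraph(
        graph=g,
        herb_components={h: frozenset(v) for h, v in herb_components.items()},
        herb_targets={h: frozenset(v) for h, v in herb_targets.items()},
        unmapped=unmapped,
    )


def merge_ctp(ct: CTGraph, ppi: nx.Graph) -> CTPGraph:
    """Union of the C-T graph and the PPI; duplicate edges collapse (max weight)."""
    components = {n for n, d in ct.graph.nodes(data=True) if d.get("kind") == "component"}
    collision = components & set(ppi.nodes)
    if collision:
        raise ValueError(
            "merge_ctp: identifier collision between component and protein namespaces: "
            f"{sorted(collision)[:5]}... — prefix the component names"
        )
    merged = nx.Graph()
    merged.add_nodes_from(ct.graph.nodes(data=True))
    merged.add_nodes_from((n, {"kind": d.get("kind", "protein")}) for n, d in ppi.nodes(data=True))
    for u, v, d in ct.graph.edges(data=True):
        merged.add_edge(u, v, weight=d.get("weight", 1.0))
    for u, v, d in ppi.edges(data=True):
        w = d.get("weight", 1.0)
        if merged.has_edge(u, v):
            merged[u][v]["weight"] = max(merged[u][v]["weight"], w)
        else:
            merged.add_edge(u, v, weight=w)
    logger.info("merge_ctp: %d nodes, %d interactions",
                merged.number_of_nodes(), merged.number_of_edges())
    return CTPGraph(graph=merged, herb_components=dict(ct.herb_components),
                    herb_targets=dict(ct.herb_targets))


def herb_mean_degree(ctp: CTPGraph, herb: str, weighted: bool = False,
                     protein_only: bool = False) -> float:
    """Arithmetic mean degree of a herb's target proteins in the merged graph.

    By default component neighbors count toward degree (degree in the full
    C-T-P graph); ``protein_only=True`` restricts to the protein subgraph.
    """
    if herb not in ctp.herb_targets or not ctp.herb_targets[herb]:
        raise KeyError(f"herb {herb!r} has no targets in the C-T-P graph")
    g = ctp.protein_subgraph() if protein_only else ctp.graph
    targets = [t for t in ctp.herb_targets[herb] if t in g]
    if not targets:
        raise KeyError(f"herb {herb!r}: no target present in graph")
    if weighted:
        degs = [sum(d["weight"] for _, _, d in g.edges(t, data=True)) for t in targets]
    else:
        degs = [g.degree(t) for t in targets]
    return float(np.mean(degs))


def all_herb_mean_degrees(ctp: CTPGraph, **kwargs) -> dict[str, float]:
    return {h: herb_mean_degree(ctp, h, **kwargs) for h in sorted(ctp.herb_targets)}
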