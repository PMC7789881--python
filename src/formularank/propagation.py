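"""Constrained shortest-path propagation from herb targets to pathogenic genes.

For every (target, pathogenic gene) pair in the protein interaction graph,
the shortest distance is computed by Dijkstra's algorithm and every tied
shortest path with at most three nodes is retained: either a direct
target-effector edge (2 nodes) or a target-mode-effector path whose
intermediate protein is called the propagation mode. The propagation
coefficient (PC) of a herb combines a mean retained-path distance per mode

    A = (sum of retained 3-node path distances) / n_modes

with a mean number of retained paths per effector

    B = (number of retained paths) / m_effectors .

The two typographically plausible readings of the statistic, PC = A * B
(default) and PC = A / B, are both available behind the ``reading`` flag and
recorded in the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .data_io import DiseaseGeneTable
from .network import CTPGraph

logger = logging.getLogger(__name__)

MAX_PATH_NODES = 3
_REL_TOL = 1e-12


@dataclass(frozen=True)
class PropagationPath:
    """A retained shortest path: (target, [mode,] effector) with its distance."""

    nodes: tuple[str, ...]
    distance: float

    def __post_init__(self) -> None:
        if not 2 <= len(self.nodes) <= 3:
            raise ValueError("PropagationPath: node count must be 2 or 3")

    @property
    def source(self) -> str:
        return self.nodes[0]

    @property
    def effector(self) -> str:
        return self.nodes[-1]

    @property
    def mode(self) -> str | None:
        return self.nodes[1] if len(self.nodes) == 3 else None


@dataclass
class PathSet:
    """All retained paths for one herb, with mode/effector bookkeeping."""

    paths: list[PropagationPath] = field(default_factory=list)
    herb: str | None = None

    @property
    def modes(self) -> frozenset[str]:
        return frozenset(p.mode for p in self.paths if p.mode is not None)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    @property
    def effectors(self) -> frozenset[str]:
        return frozenset(p.effector for p in self.paths)

    @property
    def m_effectors(self) -> int:
        return len(self.effectors)

    @property
    def effector_path_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.paths:
            counts[p.effector] = counts.get(p.effector, 0) + 1
        return counts

    def __len__(self) -> int:
        return len(self.paths)


def _validate_weights(g: nx.Graph) -> None:
    for u, v, d in g.edges(data=True):
        if d.get("weight", 1.0) <= 0:
            raise ValueError(f"edge ({u}, {v}): nonpositive weight")


def constrained_shortest_paths(g: nx.Graph, sources: Iterable[str],
                               sinks: Iterable[str],
                               max_nodes: int = MAX_PATH_NODES,
                               herb: str | None = None) -> PathSet:
    """Enumerate every tied shortest path of <= ``max_nodes`` nodes from any
    source to any sink. A source that is itself a sink contributes no path."""
    _validate_weights(g)
    sources = frozenset(sources)
    sinks = frozenset(sinks)
    if not sources or not sinks:
        raise ValueError("constrained_shortest_paths: sources and sinks must be nonempty")
    src_in = sources & set(g.nodes)
    snk_in = sinks & set(g.nodes)
    if len(src_in) < len(sources) or len(snk_in) < len(sinks):
        logger.warning("constrained_shortest_paths: dropped %d source(s) and %d sink(s) "
                       "absent from graph", len(sources) - len(src_in), len(sinks) - len(snk_in))
    ps = PathSet(herb=herb)
    for u in sorted(src_in):
        dist = nx.single_source_dijkstra_path_length(g, u, weight="weight")
        for t in sorted(snk_in):
            if t == u or t not in dist:
                continue
            d = dist[t]
            if g.has_edge(u, t) and math.isclose(g[u][t]["weight"], d, rel_tol=_REL_TOL):
                if max_nodes >= 2:
                    ps.paths.append(PropagationPath(nodes=(u, t), distance=d))
            if max_nodes >= 3:
                for m in sorted(set(g.neighbors(u)) & set(g.neighbors(t))):
                    if m in (u, t):
                        continue
                    length = g[u][m]["weight"] + g[m][t]["weight"]
                    if math.isclose(length, d, rel_tol=_REL_TOL):
                        ps.paths.append(PropagationPath(nodes=(u, m, t), distance=d))
    if not ps.paths:
        logger.warning("constrained_shortest_paths: no retained path (herb=%s)", herb)
    return ps


def propagation_coefficient(ps: PathSet, reading: str = "product") -> float:
    """Eq-style propagation coefficient of a path set; empty set scores 0."""
    if reading not in {"product", "ratio"}:
        raise ValueError(f"unknown reading {reading!r}")
    if not ps.paths:
        logger.warning("propagation_coefficient: empty path set -> 0")
        return 0.0
    three_node = [p for p in ps.paths if p.mode is not None]
    if ps.n_modes > 0:
        a = sum(p.distance for p in three_node) / ps.n_modes
    else:
        # documented fallback: no 3-node path retained, mean over direct paths
        a = sum(p.distance for p in ps.paths) / len(ps.paths)
    b = len(ps.paths) / ps.m_effectors
    return a * b if reading == "product" else a / b


def herb_propagation_report(graph: nx.Graph | CTPGraph,
                            herb_targets: Mapping[str, Iterable[str]],
                            disease: DiseaseGeneTable,
                            reading: str = "product",
                            include_components: bool = False,
                            max_nodes: int = MAX_PATH_NODES
                            ) -> dict[str, tuple[float, PathSet]]:
    """Per-herb PC with full path provenance, on the protein-only subgraph of
    the C-T-P network by default (component nodes cannot act as modes)."""
    if isinstance(graph, CTPGraph):
        g = graph.graph if include_components else graph.protein_subgraph()
    else:
        g = graph
    report: dict[str, tuple[float, PathSet]] = {}
    for herb in sorted(herb_targets):
        targets = frozenset(herb_targets[herb]) & set(g.nodes)
        if not targets:
            logger.warning("herb %s: no target present in graph, PC = 0", herb)
            report[herb] = (0.0, PathSet(herb=herb))
            continue
        sinks = disease.genes & set(g.nodes)
        if not sinks:
            report[herb] = (0.0, PathSet(herb=herb))
            continue
        ps = constrained_shortest_paths(g, targets, sinks, max_nodes=max_nodes, herb=herb)
        report[herb] = (propagation_coefficient(ps, reading=reading), ps)
    return report


def write_path_provenance(report: Mapping[str, tuple[float, PathSet]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("herb\tsource\tmode\teffector\tdistance\n")
        for herb in sorted(report):
            _, ps = report[herb]
            for p in ps.paths:
                fh.write(f"{herb}\t{p.source}\t{p.mode or ''}\t{p.effector}\t{p.distance}\n")
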