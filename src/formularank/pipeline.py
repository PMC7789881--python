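"""End-to-end orchestration: from raw tables to the herb role report."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .adme import ScreenResult, screen_adme
from .communities import (community_component_coverage, detect_communities)
from .data_io import ComponentRecord, DiseaseGeneTable, GeneSetCollection
from .enrich import hypergeom_enrich, top_pathway_contribution
from .network import CTPGraph, all_herb_mean_degrees, build_ct, merge_ctp
from .propagation import PathSet, herb_propagation_report
from .report import RoleReport, blood_overlap_rate, build_role_report, possession_rate
from .synthetic import FormulaBundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    screen: ScreenResult
    ctp: CTPGraph
    partition: dict
    mean_degree: dict[str, float]
    community_coverage: dict[str, float]
    pathway_contribution: dict[str, float]
    possession: dict[str, float]
    mean_relevance: dict[str, float]
    pc: dict[str, tuple[float, PathSet]]
    role_report: RoleReport


def run_pipeline(records: list[ComponentRecord],
                 target_map: Mapping[str, frozenset[str]],
                 ppi: nx.Graph,
                 disease: DiseaseGeneTable,
                 gene_sets: GeneSetCollection,
                 absorbed: Iterable[str] | None = None,
                 seed: int = 17,
                 n_restarts: int = 10,
                 min_community_size: int = 3,
                 k_top: int = 15,
                 reading: str = "product",
                 aggregate: str = "borda") -> PipelineResult:
    """Run every indicator family and synthesize the role ranking.

    Herbs missing from any stage (no retained component, no mappable target)
    are dropped from the final report with a warning rather than failing the
    whole run.
    """
    screen = screen_adme(records)
    totals: dict[str, int] = {}
    for r in records:
        totals[r.herb] = totals.get(r.herb, 0) + 1
    active_rate = screen.per_herb_rates(totals)

    ct = build_ct(screen.retained, target_map)
    ctp = merge_ctp(ct, ppi)
    partition = detect_communities(ctp.graph, seed=seed, n_restarts=n_restarts)
    coverage = community_component_coverage(partition, ctp, min_size=min_community_size)
    mean_degree = all_herb_mean_degrees(ctp)

    all_targets = frozenset().union(*ctp.herb_targets.values())
    enrichment = hypergeom_enrich(all_targets, gene_sets)
    contribution = top_pathway_contribution(ctp.herb_targets, enrichment, gene_sets, k_top=k_top)

    possession: dict[str, float] = {}
    mean_rel: dict[str, float] = {}
    for herb, targets in ctp.herb_targets.items():
        rate, rel = possession_rate(targets, disease)
        possession[herb] = rate
        mean_rel[herb] = 0.0 if rel is None else rel

    pc = herb_propagation_report(ctp, ctp.herb_targets, disease, reading=reading)

    herbs = sorted(set(ctp.herb_targets) & set(active_rate) & set(coverage)
                   & set(contribution) & set(mean_degree))
    dropped = sorted(set(totals) - set(herbs))
    if dropped:
        logger.warning("run_pipeline: herb(s) %s dropped from the report "
                       "(missing from one or more stages)", dropped)
    metrics: dict[str, dict[str, float]] = {
        h: {
            "active_rate": active_rate[h],
            "mean_degree": mean_degree[h],
            "community_coverage": coverage[h],
            "pathway_contribution": contribution[h],
            "possession_rate": possession[h],
            "mean_relevance": mean_rel[h],
            "propagation_coefficient": pc[h][0],
        }
        for h in herbs
    }
    if absorbed is not None:
        predicted = {h: {r.norm_name for r in screen.retained if r.herb == h} for h in herbs}
        overlap = blood_overlap_rate(predicted, absorbed)
        for h in herbs:
            metrics[h]["blood_overlap_rate"] = overlap[h]

    role = build_role_report(metrics, aggregate=aggregate)
    return PipelineResult(screen=screen, ctp=ctp, partition=partition,
                          mean_degree=mean_degree, community_coverage=coverage,
                          pathway_contribution=contribution, possession=possession,
                          mean_relevance=mean_rel, pc=pc, role_report=role)


def run_pipeline_on_bundle(bundle: FormulaBundle, seed: int = 17, **kwargs) -> PipelineResult:
    return run_pipeline(bundle.components, bundle.target_map, bundle.ppi,
                        bundle.disease, bundle.gene_sets, absorbed=bundle.absorbed,
                        seed=seed, **kwargs)
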