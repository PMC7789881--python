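"""Pathogenic-gene possession, blood-absorption overlap, and the role ranking.

The role report gathers every per-herb indicator (active-component rate,
mean degree, community coverage, pathway contribution, possession rate,
mean relevance, propagation coefficient, optional blood overlap), ranks the
herbs per indicator, and aggregates the ranks by Borda rank-sum. The herb
ranked first is annotated "Jun-like" (principal), the last "Zuo-like"
(assisting), the rest "Chen-like" — an ordering synthesized from the
indicators, not an assertion about any real prescription.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_io import DiseaseGeneTable, normalize_name

logger = logging.getLogger(__name__)


def possession_rate(herb_targets: Iterable[str],
                    disease: DiseaseGeneTable) -> tuple[float, float | None]:
    """(fraction of targets that are pathogenic genes, mean relevance of overlap).

    The mean relevance is None when the overlap is empty.
    """
    targets = frozenset(herb_targets)
    if not targets:
        raise ValueError("possession_rate: empty target set")
    overlap = targets & disease.genes
    rate = len(overlap) / len(targets)
    mean_rel = float(np.mean([disease.scores[g] for g in overlap])) if overlap else None
    return rate, mean_rel


def blood_overlap_rate(predicted: Mapping[str, Iterable[str]],
                       absorbed: Iterable[str]) -> dict[str, float]:
    """Per herb, fraction of predicted components found among blood-absorbed
    components, under normalized name matching."""
    absorbed_norm = frozenset(normalize_name(a) for a in absorbed)
    if not absorbed_norm:
        logger.warning("blood_overlap_rate: empty absorbed list, all rates 0")
    out: dict[str, float] = {}
    for herb in sorted(predicted):
        names = frozenset(normalize_name(x) for x in predicted[herb])
        if not names:
            raise ValueError(f"blood_overlap_rate: herb {herb} has no predicted components")
        out[herb] = len(names & absorbed_norm) / len(names)
    return out


ROLE_LABELS = ("Jun-like", "Chen-like", "Zuo-like")


@dataclass
class RoleReport:
    metrics: pd.DataFrame          # herbs x metrics
    ranks: pd.DataFrame            # dense per-metric ranks (1 = best)
    aggregate_scores: pd.Series    # Borda rank sums (lower = better)
    ordering: list[str]            # herbs, best first
    labels: dict[str, str] = field(default_factory=dict)
    aggregate_method: str = "borda"

    def aggregate_rank(self, herb: str) -> int:
        return self.ordering.index(herb) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "aggregate_method": self.aggregate_method,
                "ordering": self.ordering,
                "labels": self.labels,
                "metrics": {h: {m: self.metrics.loc[h, m] for m in self.metrics.columns}
                            for h in self.metrics.index},
                "ranks": {h: {m: int(self.ranks.loc[h, m]) for m in self.ranks.columns}
                          for h in self.ranks.index},
                "aggregate_scores": {h: float(self.aggregate_scores[h])
                                     for h in self.aggregate_scores.index},
                "note": ("Aggregate ordering is a Borda rank-sum synthesis of the "
                         "indicators; the Jun/Chen/Zuo-like labels annotate rank "
                         "positions only."),
            },
            indent=2,
        )


def build_role_report(metrics: Mapping[str, Mapping[str, float]],
                      directions: Mapping[str, bool] | None = None,
                      aggregate: str = "borda") -> RoleReport:
    """Rank herbs per metric (dense ranks, higher-is-better by default) and
    aggregate by Borda rank-sum (or mean z-score), ties broken by herb name."""
    if aggregate not in {"borda", "zmean"}:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    herbs = sorted(metrics)
    if not herbs:
        raise ValueError("build_role_report: no herbs")
    all_metrics = sorted({m for h in herbs for m in metrics[h]})
    for h in herbs:
        for m in all_metrics:
            if m not in metrics[h] or metrics[h][m] is None:
                raise ValueError(f"build_role_report: herb {h!r} is missing metric {m!r}")
    df = pd.DataFrame({m: [float(metrics[h][m]) for h in herbs] for m in all_metrics},
                      index=herbs)
    ranks = pd.DataFrame(index=herbs)
    for m in all_metrics:
        ascending = not (directions.get(m, True) if directions else True)
        ranks[m] = df[m].rank(method="dense", ascending=ascending).astype(int)
    if aggregate == "borda":
        scores = ranks.sum(axis=1).astype(float)
        ascending_order = True
    else:
        z = (df - df.mean()) / df.std(ddof=0).replace(0.0, 1.0)
        if directions:
            for m in all_metrics:
                if not directions.get(m, True):
                    z[m] = -z[m]
        scores = z.mean(axis=1)
        ascending_order = False
    order = scores.sort_values(ascending=ascending_order, kind="mergesort")
    # stable mergesort on a name-sorted index makes ties alphabetical
    ordering = list(order.index)
    labels = {}
    for i, h in enumerate(ordering):
        if i == 0:
            labels[h] = ROLE_LABELS[0]
        elif i == len(ordering) - 1 and len(ordering) > 1:
            labels[h] = ROLE_LABELS[2]
        else:
            labels[h] = ROLE_LABELS[1]
    return RoleReport(metrics=df, ranks=ranks, aggregate_scores=scores,
                      ordering=ordering, labels=labels, aggregate_method=aggregate)
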