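"""Hypergeometric pathway enrichment with BH-FDR and top-K target contribution.

Enrichment of a query gene set against a GMT collection uses the exact
upper-tail hypergeometric probability P(X >= k) with population N (the
background universe), K pathway genes and n query genes — no normal
approximation. Unless a universe is supplied, the background is the union
of all genes in the collection. The target-contribution statistic maps each
herb's targets onto the union of the top-K enriched pathways' genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSetCollection

logger = logging.getLogger(__name__)

ENRICH_ALPHA = 0.05
TOP_K_DEFAULT = 15


@dataclass
class EnrichmentResult:
    pathway: str
    description: str
    k: int      # overlap
    K: int      # pathway genes in background
    n: int      # query genes in background
    N: int      # background size
    p: float
    q: float    # BH-adjusted


def bh_fdr(pvalues: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    pvals = list(pvalues)
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"bh_fdr: p-value {p} outside (0, 1]")
    if not pvals:
        return []
    _, q, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(x) for x in q]


def hypergeom_enrich(query: Iterable[str], sets: GeneSetCollection,
                     background: Iterable[str] | None = None) -> list[EnrichmentResult]:
    """Exact hypergeometric enrichment of a query set, sorted by (p, pathway id)."""
    bg = frozenset(background) if background is not None else sets.all_genes()
    if not bg:
        raise ValueError("hypergeom_enrich: empty background")
    query = frozenset(query)
    outside = query - bg
    if outside:
        logger.warning("hypergeom_enrich: dropping %d query gene(s) outside background", len(outside))
    query = query & bg
    if not query:
        raise ValueError("hypergeom_enrich: no query gene in background")
    N, n = len(bg), len(query)
    results = []
    for gs in sets:
        K = len(gs.genes & bg)
        k = len(gs.genes & query)
        # upper tail P(X >= k); sf(k-1) is exact for the hypergeometric
        p = float(hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        p = min(p, 1.0)
        results.append(EnrichmentResult(pathway=gs.name, description=gs.description,
                                        k=k, K=K, n=n, N=N, p=p, q=1.0))
    results.sort(key=lambda r: (r.p, r.pathway))
    qvals = bh_fdr([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = q
    return results


def top_pathway_contribution(herb_targets: Mapping[str, Iterable[str]],
                             results: list[EnrichmentResult],
                             sets: GeneSetCollection,
                             k_top: int = TOP_K_DEFAULT,
                             alpha: float = ENRICH_ALPHA,
                             use_fdr: bool = False) -> dict[str, float]:
    """Per herb, the fraction of its targets inside the union of genes of the
    top ``k_top`` enriched pathways (raw p < alpha by default; FDR optional).

    Ties at the k-th p-value are broken by pathway id; if fewer than k_top
    pathways pass the cutoff, all passing pathways are used with a warning.
    """
    key = (lambda r: r.q) if use_fdr else (lambda r: r.p)
    passing = sorted([r for r in results if key(r) < alpha], key=lambda r: (r.p, r.pathway))
    if len(passing) < k_top:
        logger.warning("top_pathway_contribution: only %d pathway(s) pass the cutoff "
                       "(requested top %d); using all of them", len(passing), k_top)
    top = passing[:k_top]
    union: set[str] = set()
    for r in top:
        union |= sets[r.pathway].genes
    out: dict[str, float] = {}
    for herb in sorted(herb_targets):
        targets = frozenset(herb_targets[herb])
        if not targets:
            logger.warning("top_pathway_contribution: herb %s has no targets, excluded", herb)
            continue
        out[herb] = len(targets & union) / len(targets)
    return out
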