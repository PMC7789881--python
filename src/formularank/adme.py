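"""ADME screening of active components and per-herb physicochemical summaries.

Components are retained when oral bioavailability (OB) and drug-likeness
(DL) both clear their thresholds — by default OB >= 30% and DL >= 0.14,
the conventional systems-pharmacology cutoffs (both inclusive). The seven
descriptor columns (MW, ALogP, HDON, HACC, Caco-2, OB, DL) can additionally
be summarized per herb and projected by PCA to compare the chemical space
of the herbs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import DESCRIPTOR_COLUMNS, ComponentRecord

logger = logging.getLogger(__name__)

OB_MIN_DEFAULT = 30.0
DL_MIN_DEFAULT = 0.14


@dataclass
class ScreenResult:
    retained: list[ComponentRecord]
    removed: list[ComponentRecord]
    per_herb_retained: dict[str, int]
    unique_retained_names: frozenset[str]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def per_herb_rates(self, totals: dict[str, int]) -> dict[str, float]:
        """Pass rates against externally supplied pre-filter denominators.

        The unfiltered table is an input here because a post-screen table
        (like the packaged fixture) no longer carries the denominators.
        """
        return {h: self.per_herb_retained.get(h, 0) / n for h, n in totals.items() if n > 0}


def screen_adme(records: list[ComponentRecord],
                ob_min: float = OB_MIN_DEFAULT,
                dl_min: float = DL_MIN_DEFAULT) -> ScreenResult:
    """Retain components with ob >= ob_min and dl >= dl_min (both inclusive)."""
    if not records:
        raise ValueError("screen_adme: empty component list")
    if ob_min < 0 or dl_min < 0:
        raise ValueError("screen_adme: thresholds must be >= 0")
    retained, removed = [], []
    for r in records:
        (retained if r.ob >= ob_min and r.dl >= dl_min else removed).append(r)
    per_herb: dict[str, int] = {}
    for r in retained:
        per_herb[r.herb] = per_herb.get(r.herb, 0) + 1
    return ScreenResult(
        retained=retained,
        removed=removed,
        per_herb_retained=per_herb,
        unique_retained_names=frozenset(r.norm_name for r in retained),
    )


@dataclass
class PropertySummary:
    """Per-herb arithmetic descriptor means over non-missing values."""

    means: dict[str, dict[str, float]] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)


def herb_property_summary(records: list[ComponentRecord]) -> PropertySummary:
    if not records:
        raise ValueError("herb_property_summary: empty component list")
    by_herb: dict[str, list[ComponentRecord]] = {}
    for r in records:
        by_herb.setdefault(r.herb, []).append(r)
    summary = PropertySummary()
    for herb, recs in by_herb.items():
        means: dict[str, float] = {}
        counts: dict[str, int] = {}
        for col in DESCRIPTOR_COLUMNS:
            vals = [r.descriptor(col) for r in recs if r.descriptor(col) is not None]
            counts[col] = len(vals)
            if vals:
                means[col] = float(np.mean(vals))
        if not means:
            logger.warning("herb %s: no descriptor values, excluded from summary", herb)
            continue
        summary.means[herb] = means
        summary.counts[herb] = counts
    return summary


@dataclass
class PCAResult:
    scores: np.ndarray              # (n_records, n_axes)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray            # (n_kept_columns, n_axes)
    kept_columns: list[int]         # indices into the input columns
    dropped_columns: list[int]


def pca_project(matrix: np.ndarray, n_axes: int = 2) -> PCAResult:
    """Project records onto principal axes of the column-standardized matrix.

    Constant columns are dropped with a warning before standardization. The
    sign of each axis is fixed so its first nonzero loading is positive.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("pca_project: need a 2-D matrix with at least 2 records")
    std = X.std(axis=0)
    kept = [j for j in range(X.shape[1]) if std[j] > 0]
    dropped = [j for j in range(X.shape[1]) if std[j] == 0]
    if dropped:
        logger.warning("pca_project: dropping constant column(s) %s", dropped)
    if not kept:
        raise ValueError("pca_project: all columns constant")
    Z = (X[:, kept] - X[:, kept].mean(axis=0)) / std[kept]
    n_axes = min(n_axes, len(kept), X.shape[0] - 1)
    # SVD of the standardized matrix; deterministic sign convention below.
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    total_var = float((S**2).sum())
    for i in range(n_axes):
        nz = np.flatnonzero(np.abs(Vt[i]) > 1e-12)
        if nz.size and Vt[i, nz[0]] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :n_axes] * S[:n_axes]
    evr = (S[:n_axes] ** 2) / total_var
    return PCAResult(
        scores=scores,
        explained_variance_ratio=evr,
        loadings=Vt[:n_axes].T,
        kept_columns=kept,
        dropped_columns=dropped,
    )


def descriptor_matrix(records: list[ComponentRecord],
                      columns: tuple[str, ...] = DESCRIPTOR_COLUMNS) -> tuple[np.ndarray, list[str]]:
    """Records x descriptors matrix restricted to columns with no missing values."""
    usable = [c for c in columns if all(r.descriptor(c) is not None for r in records)]
    if not usable:
        raise ValueError("descriptor_matrix: no descriptor column is complete")
    X = np.array([[r.descriptor(c) for c in usable] for r in records], dtype=float)
    return X, usable
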