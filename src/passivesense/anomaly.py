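"""Day-level anomaly detection: feature matrix assembly, PCA feature
screening, and the k-Nearest-Neighbor Global Anomaly Score (GAS).

The GAS of a day is the mean Euclidean distance from its standardized
feature vector to its k nearest other days; days are ranked by descending
score and the top few flagged as anomalous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .daily_features import FeatureDay
from .synthetic_data import GroundTruth

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Standardized day x feature matrix; ``missing_mask`` marks entries
    that were imputed."""

    days: List[date]
    features: List[str]
    X: np.ndarray
    missing_mask: np.ndarray

    def restrict(self, features: Sequence[str]) -> "FeatureMatrix":
        idx = [self.features.index(f) for f in features]
        return FeatureMatrix(self.days, list(features),
                             self.X[:, idx], self.missing_mask[:, idx])


def build_matrix(feature_days: Sequence[FeatureDay],
                 impute: str = "median") -> FeatureMatrix:
    """Assemble and standardize the day x feature matrix.

    Each column is z-standardized over its non-missing entries (population
    sd); missing entries are then imputed with the median (or mean) of the
    standardized column.  Zero-variance and all-missing columns are
    dropped with a log entry.
    """
    if len(feature_days) < 2:
        raise ValueError("need at least 2 days to build a feature matrix")
    if impute not in ("median", "mean"):
        raise ValueError("impute must be 'median' or 'mean'")
    days = [fd.day for fd in feature_days]
    names = sorted({n for fd in feature_days for n in fd.values})
    raw = np.full((len(days), len(names)), np.nan)
    for i, fd in enumerate(feature_days):
        for j, n in enumerate(names):
            v = fd.values.get(n, float("nan"))
            if n not in fd.missing:
                raw[i, j] = v
    keep, cols, mask_cols = [], [], []
    for j, n in enumerate(names):
        col = raw[:, j]
        obs = ~np.isnan(col)
        if obs.sum() == 0:
            logger.info("dropping all-missing feature %s", n)
            continue
        mu = col[obs].mean()
        sd = col[obs].std()
        if sd == 0:
            logger.info("dropping zero-variance feature %s", n)
            continue
        z = (col - mu) / sd
        fill = (np.median(z[obs]) if impute == "median" else z[obs].mean())
        z[~obs] = fill
        keep.append(n)
        cols.append(z)
        mask_cols.append(~obs)
    if not keep:
        raise ValueError("no usable feature columns")
    return FeatureMatrix(days, keep, np.column_stack(cols),
                         np.column_stack(mask_cols))


def pca_screen(matrix: FeatureMatrix, variance_frac: float = 0.9,
               loading_quantile: float = 0.75) -> List[str]:
    """Select the most descriptive features by principal-component loadings.

    Keep the leading components explaining at least ``variance_frac`` of
    the variance; a feature survives when its maximum absolute loading
    across the kept components reaches the ``loading_quantile`` quantile
    of all such maxima.  The selection is never empty (fallback: top 5 by
    max loading).
    """
    if not (0 < variance_frac <= 1):
        raise ValueError("variance_frac must be in (0, 1]")
    n_days, n_feat = matrix.X.shape
    n_comp = min(n_days - 1, n_feat)
    if n_comp < n_feat:
        logger.warning("only %d days for %d features; using %d components",
                       n_days, n_feat, n_comp)
    pca = PCA(n_components=n_comp)
    pca.fit(matrix.X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_frac - 1e-12) + 1)
    n_keep = min(n_keep, n_comp)
    # Factor-analysis loadings: eigenvectors scaled by the component sd,
    # i.e. the correlation of each feature with each component.  Without
    # the scaling, features carrying only their own noise dominate.
    sd = np.sqrt(pca.explained_variance_[:n_keep])
    loadings = np.abs(pca.components_[:n_keep]) * sd[:, None]
    max_load = loadings.max(axis=0)
    thr = np.quantile(max_load, loading_quantile)
    selected = [f for f, m in zip(matrix.features, max_load) if m >= thr]
    if not selected:
        order = np.argsort(-max_load)[:5]
        selected = [matrix.features[i] for i in order]
    return selected


@dataclass
class AnomalyReport:
    days: List[date]
    scores: np.ndarray
    ranking: List[date]            # descending score, ties by day order
    flagged: List[date]
    k: int
    selected_features: List[str] = field(default_factory=list)

    def score_of(self, day: date) -> float:
        return float(self.scores[self.days.index(day)])


def knn_gas(matrix: FeatureMatrix, k: int = 5,
            features: Optional[Sequence[str]] = None,
            flag_fraction: float = 0.05) -> AnomalyReport:
    """Score each day by the mean Euclidean distance to its k nearest
    other days and flag the top ``ceil(flag_fraction * n)`` (min 1)."""
    fm = matrix.restrict(features) if features is not None else matrix
    n = len(fm.days)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must satisfy 1 <= k <= n_days - 1 (k={k}, days={n})")
    D = cdist(fm.X, fm.X)
    np.fill_diagonal(D, np.inf)
    part = np.partition(D, k - 1, axis=1)[:, :k]
    scores = part.mean(axis=1)
    order = np.lexsort((np.arange(n), -scores))
    ranking = [fm.days[i] for i in order]
    m = max(1, math.ceil(flag_fraction * n))
    return AnomalyReport(days=list(fm.days), scores=scores, ranking=ranking,
                         flagged=ranking[:m], k=k,
                         selected_features=list(fm.features))


@dataclass
class RegimeRecovery:
    n_holidays: int
    holidays_in_top: Optional[int]     # holidays among the top_n ranks
    top_n: int
    holiday_recall: Optional[float]
    separation: Optional[float]        # median GAS holidays - workdays


def recover_regimes(report: AnomalyReport, truth: GroundTruth,
                    top_n: int = 5) -> RegimeRecovery:
    """How well the anomaly ranking recovers the injected holiday days."""
    holidays = [d for d in truth.holidays() if d in report.days]
    workdays = [d for d, r in truth.regime_calendar.items()
                if r == "workday" and d in report.days]
    if not holidays:
        return RegimeRecovery(0, None, top_n, None, None)
    top = set(report.ranking[:top_n])
    hit = sum(1 for d in holidays if d in top)
    sep = None
    if workdays:
        sep = (float(np.median([report.score_of(d) for d in holidays]))
               - float(np.median([report.score_of(d) for d in workdays])))
    return RegimeRecovery(len(holidays), hit, top_n,
                          hit / len(holidays), sep)
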