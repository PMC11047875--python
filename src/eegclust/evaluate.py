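"""Clustering quality indices and coefficient-of-variation composite scoring.

The three internal validity indices (silhouette, Calinski-Harabasz,
Davies-Bouldin) are computed from scratch so their degenerate-case
conventions are explicit.  The composite scorer turns an
algorithms-by-indicators table into a single ranking: negative indicators
are positivized, every column is normalized, and each indicator is
weighted by its coefficient of variation across the evaluated algorithms
(high spread = high discriminative value = high weight).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "MetricTable",
    "silhouette_coefficient",
    "silhouette_samples",
    "calinski_harabasz",
    "davies_bouldin",
    "cv_composite",
]


def _split_clusters(labels: np.ndarray) -> list[np.ndarray]:
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    return [np.where(labels == u)[0] for u in uniq]


def silhouette_samples(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette values ``(b-a)/max(a,b)``.

    ``a`` is the mean distance to the sample's own cluster (excluding
    itself), ``b`` the smallest mean distance to any other cluster.
    Samples in singleton clusters contribute 0.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] != len(labels):
        raise ValueError("points and labels must align")
    clusters = _split_clusters(labels)
    dist = squareform(pdist(points))
    s = np.zeros(points.shape[0])
    for ci, members in enumerate(clusters):
        size = members.size
        for i in members:
            if size == 1:
                s[i] = 0.0
                continue
            a = dist[i, members].sum() / (size - 1)
            b = min(
                dist[i, other].mean()
                for cj, other in enumerate(clusters)
                if cj != ci
            )
            s[i] = (b - a) / max(a, b)
    return s


def silhouette_coefficient(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette over all samples; in [-1, 1]."""
    return float(np.mean(silhouette_samples(points, labels)))


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """Between- over within-cluster scatter ratio.

    ``[tr(B)/(k-1)] / [tr(W)/(n-k)]``; zero within-cluster scatter gives
    ``inf``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    clusters = _split_clusters(labels)
    k = len(clusters)
    n = points.shape[0]
    overall = points.mean(axis=0)
    tr_b = sum(
        m.size * float(np.sum((points[m].mean(axis=0) - overall) ** 2))
        for m in clusters
    )
    tr_w = sum(
        float(np.sum((points[m] - points[m].mean(axis=0)) ** 2))
        for m in clusters
    )
    if tr_w == 0.0:
        return np.inf
    return (tr_b / (k - 1)) / (tr_w / (n - k))


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst intra/inter dispersion ratio.

    ``mean_i max_{j!=i} (S_i + S_j) / ||c_i - c_j||`` with S the mean
    Euclidean distance to the cluster centroid; lower is better.
    Coincident centroids give ``inf``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    clusters = _split_clusters(labels)
    centroids = np.vstack([points[m].mean(axis=0) for m in clusters])
    spread = np.array(
        [
            float(np.mean(np.linalg.norm(points[m] - centroids[ci], axis=1)))
            for ci, m in enumerate(clusters)
        ]
    )
    gap = cdist(centroids, centroids)
    k = len(clusters)
    worst = np.empty(k)
    for i in range(k):
        ratios = []
        for j in range(k):
            if j == i:
                continue
            if gap[i, j] == 0.0:
                return np.inf
            ratios.append((spread[i] + spread[j]) / gap[i, j])
        worst[i] = max(ratios)
    return float(np.mean(worst))


@dataclass
class MetricTable:
    """Algorithms-by-indicators table with per-indicator polarity.

    polarity: "positive" (bigger is better) or "negative" (smaller is
    better) per indicator column.
    """

    object_names: list[str]
    indicator_names: list[str]
    values: np.ndarray
    polarity: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, j = self.values.shape
        if m < 2 or j < 1:
            raise ValueError("need >= 2 objects and >= 1 indicator")
        if len(self.object_names) != m or len(self.indicator_names) != j:
            raise ValueError("names do not match table shape")
        if len(self.polarity) != j:
            raise ValueError("polarity must have one entry per indicator")
        if any(p not in ("positive", "negative") for p in self.polarity):
            raise ValueError("polarity entries must be 'positive' or 'negative'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("table contains non-finite values")


def _positivize(col: np.ndarray, how: str) -> np.ndarray:
    if how == "max_minus":
        return col.max() - col
    if how == "reciprocal":
        if np.any(col == 0):
            raise ValueError("reciprocal inversion hit a zero value")
        return 1.0 / col
    if how == "rev_minmax":
        rng = col.max() - col.min()
        if rng == 0:
            return np.zeros_like(col)
        return (col.max() - col) / rng
    raise ValueError(f"unknown inversion {how!r}")


def _normalize(col: np.ndarray, how: str) -> np.ndarray:
    if how == "vector":
        norm = float(np.sqrt(np.sum(col**2)))
        if norm == 0:
            raise ValueError("cannot vector-normalize an all-zero indicator")
        return col / norm
    if how == "max":
        if col.max() == 0:
            raise ValueError("cannot max-normalize an all-zero indicator")
        return col / col.max()
    if how == "sum":
        if col.sum() == 0:
            raise ValueError("cannot sum-normalize a zero-sum indicator")
        return col / col.sum()
    if how == "minmax":
        rng = col.max() - col.min()
        if rng == 0:
            raise ValueError("cannot min-max normalize a constant indicator")
        return (col - col.min()) / rng
    raise ValueError(f"unknown normalization {how!r}")


def cv_composite(
    table: MetricTable,
    inversion: str = "max_minus",
    normalization: str = "vector",
    std: str = "population",
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient-of-variation weights and composite scores.

    Steps: positivize negative indicators (``max_minus`` by default:
    ``max - x``; ``reciprocal`` and ``rev_minmax`` available), normalize
    every indicator column (``vector`` by default; ``max``, ``sum`` and
    ``minmax`` available), then per indicator j compute the mean A_j, the
    standard deviation S_j (population by default), the coefficient of
    variation ``V_j = S_j / A_j`` and the weight ``W_j = V_j / sum(V)``.
    Object i scores ``sum_j W_j r_ij``.

    Returns ``(weights, scores)``; weights sum to 1.
    """
    if std not in ("population", "sample"):
        raise ValueError("std must be 'population' or 'sample'")
    m, j = table.values.shape
    r = np.empty_like(table.values)
    for col in range(j):
        c = table.values[:, col].copy()
        if table.polarity[col] == "negative":
            c = _positivize(c, inversion)
        r[:, col] = _normalize(c, normalization)
    a = r.mean(axis=0)
    if np.any(a == 0):
        bad = table.indicator_names[int(np.argmax(a == 0))]
        raise ValueError(f"indicator {bad!r} has zero mean after normalization")
    ddof = 0 if std == "population" else 1
    s = r.std(axis=0, ddof=ddof)
    v = s / a
    total = v.sum()
    if total == 0:
        raise ValueError("all indicators are constant; weights undefined")
    weights = v / total
    scores = r @ weights
    return weights, scores
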