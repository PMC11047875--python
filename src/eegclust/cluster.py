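"""Density clustering with metaheuristic hyperparameter selection.

DBSCAN is implemented with a self-inclusive neighborhood count and an
order-invariant border rule (a border point joins the cluster of its
nearest core point), so the partition depends only on the point set and
the (Eps, MinPts) pair.  The sparrow search algorithm (SSA) — a swarm
optimizer with explorer, follower and alarmed-sparrow update rules —
searches that parameter plane, scoring each candidate by the silhouette
of the resulting labeling (noise excluded).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .evaluate import silhouette_coefficient

__all__ = [
    "ClusterResult",
    "SSAParams",
    "SearchBounds",
    "region_query",
    "dbscan",
    "clustering_fitness",
    "ssa_optimize",
    "ssa_dbscan",
]

NOISE = -1


@dataclass
class ClusterResult:
    """Labels (noise = -1) plus the parameters that produced them."""

    labels: np.ndarray
    eps: float
    min_pts: int
    fitness: float
    n_clusters: int
    valid: bool = True

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        distinct = np.unique(self.labels[self.labels != NOISE])
        if distinct.size != self.n_clusters:
            raise ValueError("n_clusters does not match the labeling")
        if distinct.size and not np.array_equal(distinct, np.arange(distinct.size)):
            raise ValueError("cluster labels must be consecutive from 0")


@dataclass
class SSAParams:
    """Sparrow search controls.

    iter_max : number of iterations
    pop : population size
    st : safety threshold in (0.5, 1]; below it explorers sweep smoothly,
        above it they scatter with Gaussian steps
    explorer_count : number of best-ranked sparrows acting as explorers
        (defaults to 20% of the population)
    alarm_fraction : fraction of the population alarmed each iteration
    """

    iter_max: int = 50
    pop: int = 30
    st: float = 0.8
    explorer_count: int | None = None
    alarm_fraction: float = 0.2
    eps_guard: float = 1e-50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iter_max < 1 or self.pop < 1:
            raise ValueError("iter_max and pop must be >= 1")
        if not 0.5 < self.st <= 1.0:
            raise ValueError("st must lie in (0.5, 1.0]")
        if self.explorer_count is None:
            self.explorer_count = max(1, int(np.ceil(0.2 * self.pop)))
        if self.explorer_count >= self.pop + 1:
            raise ValueError("explorer_count must not exceed the population")
        if not 0 < self.alarm_fraction <= 1:
            raise ValueError("alarm_fraction must lie in (0, 1]")


@dataclass
class SearchBounds:
    """Rectangular (Eps, MinPts) search region."""

    eps_range: tuple[float, float]
    minpts_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 < self.eps_range[0] < self.eps_range[1]:
            raise ValueError("eps_range must satisfy 0 < low < high")
        if not 0 < self.minpts_range[0] < self.minpts_range[1]:
            raise ValueError("minpts_range must satisfy 0 < low < high")


def region_query(points: np.ndarray, index: int, eps: float) -> np.ndarray:
    """Indices (self-inclusive) within Euclidean distance ``eps`` of a point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not 0 <= index < points.shape[0]:
        raise IndexError(f"index {index} out of range")
    if eps <= 0:
        raise ValueError("eps must be positive")
    d = np.linalg.norm(points - points[index], axis=1)
    return np.where(d <= eps)[0]


def dbscan(points: np.ndarray, eps: float, min_pts: int) -> ClusterResult:
    """Density-based clustering with deterministic border assignment.

    Core points (self-inclusive neighborhood of at least ``min_pts``) are
    grouped into the connected components of the core-core Eps graph;
    border points join the cluster of the nearest core point; everything
    else is noise.  The partition is invariant to input order, and clusters
    are numbered by their smallest member index.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n == 0:
        raise ValueError("empty input")
    if eps <= 0 or min_pts < 1:
        raise ValueError("eps must be > 0 and min_pts >= 1")
    dist = squareform(pdist(points))
    adj = dist <= eps
    counts = adj.sum(axis=1)  # self-inclusive
    core = counts >= min_pts
    labels = np.full(n, NOISE)
    cluster = 0
    for start in range(n):
        if not core[start] or labels[start] != NOISE:
            continue
        # BFS over the core-core graph
        stack = [start]
        labels[start] = cluster
        while stack:
            p = stack.pop()
            for q in np.where(adj[p] & core)[0]:
                if labels[q] == NOISE:
                    labels[q] = cluster
                    stack.append(q)
        cluster += 1
    core_idx = np.where(core)[0]
    if core_idx.size:
        for p in range(n):
            if core[p] or labels[p] != NOISE:
                continue
            reach = core_idx[adj[p, core_idx]]
            if reach.size:
                nearest = reach[np.argmin(dist[p, reach])]
                labels[p] = labels[nearest]
    fitness = clustering_fitness(points, labels)
    return ClusterResult(
        labels=labels, eps=float(eps), min_pts=int(min_pts),
        fitness=fitness, n_clusters=cluster,
    )


def clustering_fitness(points: np.ndarray, labels: np.ndarray) -> float:
    """Noise-penalized silhouette of the labeling.

    The silhouette is computed over non-noise points only and multiplied
    by the assigned (non-noise) fraction.  Without the penalty the search
    converges on labelings that declare most points noise and keep a few
    ultra-tight cores, which score a near-perfect silhouette while
    discarding the data.  Labelings with no noise are scored by the plain
    silhouette.  Returns -1 when there are fewer than 2 clusters or fewer
    than 3 non-noise points, so degenerate labelings rank below any real
    one.
    """
    labels = np.asarray(labels, dtype=int)
    mask = labels != NOISE
    if mask.sum() < 3 or np.unique(labels[mask]).size < 2:
        return -1.0
    points = np.atleast_2d(np.asarray(points, dtype=float))
    sil = silhouette_coefficient(points[mask], labels[mask])
    return sil * (mask.sum() / labels.size)


def ssa_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    params: SSAParams | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``objective`` over a box with the sparrow search algorithm.

    Per iteration the population is ranked; the best-ranked sparrows act as
    explorers (exponential-decay sweep while the random alarm R2 stays
    below the safety threshold, Gaussian scatter otherwise), the rest
    follow (worst-relative exponential move for the lower-ranked half,
    best-anchored random-sign averaged move for the upper half), and a
    random subset reacts to danger by moving relative to the global best
    and worst.  Positions are clamped to the bounds after every update.
    Non-finite objective values are treated as +inf.

    Returns ``(best position, best value, per-iteration best-so-far trace)``.
    """
    params = params or SSAParams()
    lows = np.array([b[0] for b in bounds], dtype=float)
    highs = np.array([b[1] for b in bounds], dtype=float)
    if lows.size < 1 or np.any(lows >= highs):
        raise ValueError("bounds must satisfy low < high per dimension")
    dim = lows.size
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.pop

    def safe_eval(pos: np.ndarray) -> float:
        val = objective(pos)
        return float(val) if np.isfinite(val) else np.inf

    x = rng.uniform(lows, highs, size=(n, dim))
    f = np.array([safe_eval(xi) for xi in x])
    best_idx = int(np.argmin(f))
    best_x, best_f = x[best_idx].copy(), float(f[best_idx])
    trace = np.empty(params.iter_max)

    for t in range(params.iter_max):
        order = np.argsort(f, kind="stable")
        x, f = x[order], f[order]
        xb, xw = x[0].copy(), x[-1].copy()
        fg, fw = float(f[0]), float(f[-1])

        r2 = rng.uniform(0.0, 1.0)
        pn = min(params.explorer_count, n)
        for i in range(pn):
            if r2 < params.st:
                alpha = rng.uniform(np.finfo(float).tiny, 1.0)
                x[i] = x[i] * np.exp(-(i + 1) / (alpha * params.iter_max))
            else:
                x[i] = x[i] + rng.standard_normal(dim)
        for i in range(pn, n):
            if (i + 1) > n / 2:
                q = rng.standard_normal()
                alpha = rng.uniform(np.finfo(float).tiny, 1.0)
                # exponent clipped: huge arguments would overflow and the
                # position is clamped to the bounds right after anyway
                arg = np.clip((xw - x[i]) / (alpha * params.iter_max), -50.0, 50.0)
                x[i] = q * np.exp(arg)
            else:
                signs = rng.choice([-1.0, 1.0], size=dim)
                step = float(np.mean(signs * (xb - x[i])))
                x[i] = xb + step
        n_alarm = max(1, int(round(params.alarm_fraction * n)))
        for i in rng.choice(n, size=n_alarm, replace=False):
            if f[i] != fg:
                beta = rng.standard_normal()
                x[i] = xb + beta * (x[i] - xb)
            else:
                k = rng.uniform(-1.0, 1.0)
                x[i] = x[i] + k * (x[i] - xw) / (abs(f[i] - fw) + params.eps_guard)
        np.clip(x, lows, highs, out=x)
        f = np.array([safe_eval(xi) for xi in x])
        it_best = int(np.argmin(f))
        if f[it_best] < best_f:
            best_f = float(f[it_best])
            best_x = x[it_best].copy()
        trace[t] = best_f
    return best_x, best_f, trace


def default_bounds(points: np.ndarray) -> SearchBounds:
    """Data-driven (Eps, MinPts) box: Eps spans the 1st-99th percentile of
    pairwise distances; MinPts spans 2 to min(50, n/3)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = pdist(points)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all points coincide; no distance scale")
    lo, hi = np.percentile(d, [1, 99])
    if lo <= 0:
        lo = float(d.min())
    n = points.shape[0]
    return SearchBounds(
        eps_range=(float(lo), float(hi)),
        minpts_range=(2, max(3, min(50, n // 3))),
    )


def ssa_dbscan(
    points: np.ndarray,
    bounds: SearchBounds | None = None,
    params: SSAParams | None = None,
) -> ClusterResult:
    """Adaptive DBSCAN: sparrow search over (Eps, MinPts).

    The continuous MinPts coordinate is decoded by nearest-integer
    rounding; the objective is the negative silhouette fitness of the
    DBSCAN labeling, and every evaluated labeling is cached so the best
    one is returned without recomputation.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 5:
        raise ValueError("need at least 5 points")
    bounds = bounds or default_bounds(points)
    params = params or SSAParams()
    cache: dict[tuple[float, int], ClusterResult] = {}

    def decode(pos: np.ndarray) -> tuple[float, int]:
        eps = float(pos[0])
        mp = int(round(pos[1]))
        mp = min(max(mp, bounds.minpts_range[0]), bounds.minpts_range[1])
        return eps, mp

    def objective(pos: np.ndarray) -> float:
        eps, mp = decode(pos)
        key = (round(eps, 12), mp)
        if key not in cache:
            cache[key] = dbscan(points, eps, mp)
        return -cache[key].fitness

    box = [
        (bounds.eps_range[0], bounds.eps_range[1]),
        (float(bounds.minpts_range[0]), float(bounds.minpts_range[1])),
    ]
    best_pos, best_val, _trace = ssa_optimize(objective, box, params)
    eps, mp = decode(best_pos)
    result = cache[(round(eps, 12), mp)]
    if result.fitness <= -1.0:
        warnings.warn("no valid clustering found in the search range", stacklevel=2)
        result.valid = False
    return result
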