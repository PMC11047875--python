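"""Exact t-SNE embedding of the feature matrix to 2-D or 3-D.

High-dimensional affinities are Gaussian with per-point bandwidths
calibrated by bisection to a target perplexity; low-dimensional
similarities use the heavy-tailed Student-t kernel ``1/(1+d^2)``.  The
KL divergence between the two is minimized by gradient descent with
momentum, adaptive gains and an early-exaggeration phase.  Gradients are
exact (no tree approximation): the intended scale is a few hundred
segments.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .features import FeatureMatrix

__all__ = ["Embedding", "perplexity_calibration", "tsne_embed"]

_EPS = 1e-12


@dataclass
class Embedding:
    """Low-dimensional coordinates plus the per-iteration KL trace."""

    coords: np.ndarray
    kl_trace: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.kl_trace = np.asarray(self.kl_trace, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains non-finite coordinates")


def perplexity_calibration(
    distances: np.ndarray, perplexity: float, tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Row-stochastic Gaussian affinities at a fixed perplexity.

    For each row a bandwidth (precision beta) is found by bisection so the
    row entropy H satisfies ``2**H = perplexity`` (|H - log2(perplexity)|
    below ``tol``).  The diagonal is zero and every row sums to 1.
    Squared distances are shifted by the row minimum before exponentiation
    so the weights never underflow collectively.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distances must be square")
    if not 1.0 < perplexity < n:
        raise ValueError(f"perplexity must lie in (1, {n})")
    d2 = d**2
    p = np.zeros((n, n))
    log_target = np.log2(perplexity)
    for i in range(n):
        row = np.delete(d2[i], i)
        row = row - row.min()  # shift-invariant after normalization
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        for _ in range(max_iter):
            w = np.exp(-row * beta)
            pi = w / w.sum()
            h = -np.sum(pi[pi > 0] * np.log2(pi[pi > 0]))
            diff = h - log_target
            if abs(diff) < tol:
                break
            if diff > 0:  # entropy too high -> sharpen
                beta_lo = beta
                beta = beta * 2 if np.isinf(beta_hi) else (beta_lo + beta_hi) / 2
            else:
                beta_hi = beta
                beta = beta / 2 if beta_lo == 0.0 else (beta_lo + beta_hi) / 2
        w = np.exp(-row * beta)
        pi = w / w.sum()
        p[i] = np.insert(pi, i, 0.0)
    return p


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / np.maximum(q[mask], _EPS))))


def tsne_embed(
    features: FeatureMatrix | np.ndarray,
    d: int = 2,
    perplexity: float = 30.0,
    iters: int = 1000,
    seed: int = 0,
    learning_rate: float = 200.0,
    early_exaggeration: float = 12.0,
    exaggeration_iters: int = 250,
    init: np.ndarray | None = None,
) -> Embedding:
    """Embed the feature matrix with exact-gradient t-SNE.

    Deterministic given ``seed``; the requested perplexity is clamped to
    ``(n-1)/3`` when the sample is small.  ``init`` overrides the random
    Gaussian initialization (scaled 1e-4), which makes permutation and
    reproducibility checks possible.
    """
    x = features.values if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain non-finite values")
    n = x.shape[0]
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if n < 5:
        raise ValueError("need at least 5 points")
    perplexity = min(perplexity, (n - 1) / 3.0)
    perplexity = max(perplexity, 1.0 + 1e-6)

    dist = squareform(pdist(x))
    p_cond = perplexity_calibration(dist, perplexity)
    p = (p_cond + p_cond.T) / (2.0 * n)
    p = np.maximum(p, _EPS)
    np.fill_diagonal(p, 0.0)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = (
        np.array(init, dtype=float, copy=True)
        if init is not None
        else 1e-4 * rng.standard_normal((n, d))
    )
    if y.shape != (n, d):
        raise ValueError("init shape must be (n, d)")

    update = np.zeros_like(y)
    gains = np.ones_like(y)
    kl_trace = np.empty(iters)
    for t in range(iters):
        exag = early_exaggeration if t < exaggeration_iters else 1.0
        momentum = 0.5 if t < exaggeration_iters else 0.8
        diff = y[:, None, :] - y[None, :, :]
        w = 1.0 / (1.0 + np.sum(diff**2, axis=2))
        np.fill_diagonal(w, 0.0)
        q = w / w.sum()
        grad_coef = (exag * p - q) * w
        grad = 4.0 * np.einsum("ij,ijk->ik", grad_coef, diff)
        sign_agree = np.sign(grad) == np.sign(update)
        gains = np.where(sign_agree, gains * 0.8, gains + 0.2)
        gains = np.maximum(gains, 0.01)
        update = momentum * update - learning_rate * gains * grad
        y = y + update
        y = y - y.mean(axis=0)
        kl_trace[t] = _kl(p, np.maximum(q, _EPS))
    return Embedding(coords=y, kl_trace=kl_trace, seed=seed)
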