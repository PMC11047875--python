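"""Empirical mode decomposition family: EMD, EEMD and CEEMDAN.

All three decompose a segment into intrinsic mode functions (IMFs) ordered
from highest to lowest instantaneous frequency, plus a residue.  Sifting
uses cubic-spline extremum envelopes with mirrored boundary extension and a
Cauchy-style stopping rule.  EEMD averages the modes of noise-perturbed
copies of the signal; CEEMDAN injects, at stage k, the k-th EMD mode of the
white-noise realizations into the running residue, which restores the exact
reconstruction identity that plain EEMD loses.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .segment import SignalSegment

__all__ = [
    "SiftConfig",
    "IMFSet",
    "DecompositionError",
    "emd",
    "eemd",
    "ceemdan",
]


class DecompositionError(ValueError):
    """Raised when a signal cannot be sifted (constant, too short, ...)."""


@dataclass
class SiftConfig:
    """Sifting controls.

    max_imfs : hard cap on the number of extracted modes
    max_sift_iters : iteration cap per mode
    stop_threshold : Cauchy criterion — stop sifting once the normalized
        squared difference between successive sift iterates falls below it
    boundary : extremum-envelope boundary policy (only ``"mirror"``:
        two extrema mirrored about each end)
    """

    max_imfs: int = 10
    max_sift_iters: int = 50
    stop_threshold: float = 0.2
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")
        if self.boundary != "mirror":
            raise ValueError(f"unknown boundary policy {self.boundary!r}")


@dataclass
class IMFSet:
    """Ordered IMFs (rows, high to low frequency) plus the residue."""

    imfs: np.ndarray  # K x N
    residue: np.ndarray  # N
    source_length: int

    def __post_init__(self) -> None:
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        self.residue = np.asarray(self.residue, dtype=float)
        if self.imfs.shape[1] != self.source_length:
            raise ValueError("IMF length does not match source length")
        if self.residue.size != self.source_length:
            raise ValueError("residue length does not match source length")

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residue


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima, plateau-aware."""
    d = np.sign(np.diff(x))
    # propagate through zero-slope plateaus so a flat top counts once
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    turn = np.diff(d)
    maxima = np.where(turn < 0)[0] + 1
    minima = np.where(turn > 0)[0] + 1
    return maxima, minima


def _mirrored(idx: np.ndarray, val: np.ndarray, n: int, pad: int = 2):
    """Extend extrema by mirroring ``pad`` of them about each endpoint."""
    k = min(pad, idx.size)
    left_t = 2 * 0 - idx[:k][::-1]
    left_v = val[:k][::-1]
    right_t = 2 * (n - 1) - idx[-k:][::-1]
    right_v = val[-k:][::-1]
    t = np.concatenate([left_t, idx, right_t])
    v = np.concatenate([left_v, val, right_v])
    # mirroring can duplicate a boundary extremum; keep strictly increasing t
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper/lower cubic-spline envelopes, or None if the
    signal has too few extrema to build them."""
    n = x.size
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    t_up, v_up = _mirrored(maxima, x[maxima], n)
    t_lo, v_lo = _mirrored(minima, x[minima], n)
    grid = np.arange(n)
    upper = CubicSpline(t_up, v_up)(grid)
    lower = CubicSpline(t_lo, v_lo)(grid)
    return 0.5 * (upper + lower)


def _sift(x: np.ndarray, cfg: SiftConfig) -> np.ndarray | None:
    """Extract one IMF from ``x`` or return None if ``x`` is a residue."""
    h = x
    m = _mean_envelope(h)
    if m is None:
        return None
    for _ in range(cfg.max_sift_iters):
        h_new = h - m
        denom = float(np.sum(h**2))
        sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
        h = h_new
        if sd < cfg.stop_threshold:
            break
        m = _mean_envelope(h)
        if m is None:
            break
    return h


def _emd_array(x: np.ndarray, cfg: SiftConfig) -> list[np.ndarray]:
    """All IMFs of a plain array (no residue in the returned list)."""
    imfs: list[np.ndarray] = []
    r = x.astype(float).copy()
    while len(imfs) < cfg.max_imfs:
        imf = _sift(r, cfg)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
    return imfs


def _validate(signal: SignalSegment) -> np.ndarray:
    x = np.asarray(signal.samples, dtype=float)
    if np.ptp(x) == 0:
        raise DecompositionError(
            f"segment {signal.id!r} is constant; nothing to decompose"
        )
    return x


def emd(signal: SignalSegment, cfg: SiftConfig | None = None) -> IMFSet:
    """Plain empirical mode decomposition by iterative sifting.

    The IMFs and residue telescope back to the input, so the reconstruction
    identity holds to machine precision.
    """
    cfg = cfg or SiftConfig()
    x = _validate(signal)
    imfs = _emd_array(x, cfg)
    if not imfs:
        raise DecompositionError(
            f"segment {signal.id!r} yields no IMF (too few extrema)"
        )
    stack = np.vstack(imfs)
    residue = x - stack.sum(axis=0)
    return IMFSet(imfs=stack, residue=residue, source_length=x.size)


def _stack_ragged(imf_lists: list[list[np.ndarray]], n: int) -> np.ndarray:
    """Average IMF lists of unequal depth, padding missing modes with zeros."""
    k = max(len(lst) for lst in imf_lists)
    out = np.zeros((k, n))
    for lst in imf_lists:
        for i, imf in enumerate(lst):
            out[i] += imf
    return out / len(imf_lists)


def eemd(
    signal: SignalSegment,
    ensemble_size: int = 100,
    noise_ratio: float = 0.2,
    seed: int = 0,
    cfg: SiftConfig | None = None,
) -> IMFSet:
    """Ensemble EMD: average the EMD modes of noise-perturbed copies.

    ``noise_ratio`` scales the added white noise as a fraction of the signal
    standard deviation.  The averaged modes do not sum exactly back to the
    input; the residual discrepancy shrinks as the ensemble grows.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if noise_ratio < 0:
        raise ValueError("noise_ratio must be >= 0")
    cfg = cfg or SiftConfig()
    x = _validate(signal)
    if noise_ratio == 0.0 and ensemble_size == 1:
        return emd(signal, cfg)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = noise_ratio * float(np.std(x))
    imf_lists = []
    residues = []
    for _ in range(ensemble_size):
        noisy = x + sigma * rng.standard_normal(x.size)
        imfs = _emd_array(noisy, cfg)
        if not imfs:
            raise DecompositionError("an ensemble member yielded no IMF")
        imf_lists.append(imfs)
        residues.append(noisy - np.sum(imfs, axis=0))
    stack = _stack_ragged(imf_lists, x.size)
    residue = np.mean(residues, axis=0)
    return IMFSet(imfs=stack, residue=residue, source_length=x.size)


def ceemdan(
    signal: SignalSegment,
    ensemble_size: int = 100,
    noise_ratio: float = 0.2,
    seed: int = 0,
    cfg: SiftConfig | None = None,
    noise_decay: float = 0.9,
) -> IMFSet:
    """Complete ensemble EMD with adaptive noise.

    Stage k adds the k-th EMD mode of each white-noise realization, scaled by
    ``noise_ratio * std(signal) * noise_decay**k``, to the current residue;
    the ensemble mean of the first sifted mode becomes IMF_k and is
    subtracted from the residue.  Because each IMF is subtracted from the
    running residue, ``sum(imfs) + residue`` equals the input exactly.

    With ``noise_ratio = 0`` the procedure reduces to plain EMD.
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be >= 1")
    if noise_ratio < 0:
        raise ValueError("noise_ratio must be >= 0")
    cfg = cfg or SiftConfig()
    x = _validate(signal)
    n = x.size
    if noise_ratio == 0.0:
        out = emd(signal, cfg)
        return out
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma0 = noise_ratio * float(np.std(x))
    # pre-decompose every unit-variance noise realization once
    noise_modes = []
    for _ in range(ensemble_size):
        w = rng.standard_normal(n)
        noise_modes.append(_emd_array(w, cfg))

    imfs: list[np.ndarray] = []
    r = x.copy()
    for k in range(cfg.max_imfs):
        amp = sigma0 * noise_decay**k
        first_modes = []
        for modes in noise_modes:
            carrier = modes[k] if k < len(modes) else None
            perturbed = r + amp * carrier if carrier is not None else r
            imf = _sift(perturbed, cfg)
            if imf is not None:
                first_modes.append(imf)
        if not first_modes:
            break
        imf_k = np.mean(first_modes, axis=0)
        imfs.append(imf_k)
        r = r - imf_k
        maxima, minima = _local_extrema(r)
        if maxima.size < 2 or minima.size < 2:
            break
    if not imfs:
        raise DecompositionError(
            f"segment {signal.id!r} yields no IMF (too few extrema)"
        )
    return IMFSet(imfs=np.vstack(imfs), residue=r, source_length=n)


def zero_crossing_rate(x: np.ndarray) -> float:
    """Zero crossings per sample; used to check IMF frequency ordering."""
    s = np.sign(x)
    s[s == 0] = 1
    return float(np.count_nonzero(np.diff(s))) / max(x.size - 1, 1)
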