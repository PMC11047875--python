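"""Multivariate feature extraction for EEG segments.

Twelve features per segment spanning time, frequency, time-frequency and
nonlinear families: mean, RMS, skewness, fluctuation index, the three
Hjorth parameters, Shannon entropy, mean Teager energy, two relative band
powers (theta+alpha 4-13 Hz, beta+gamma 13-45 Hz) and wavelet energy
entropy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps
from scipy import stats

from .denoise import WaveletSpec
from .segment import SignalSegment

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "basic_stats",
    "hjorth",
    "shannon_entropy",
    "mean_teager_energy",
    "fluctuation_index",
    "spectral_features",
    "wavelet_subband_features",
    "extract_feature_matrix",
    "DEFAULT_FEATURE_NAMES",
]

DEFAULT_BANDS: tuple[tuple[float, float], ...] = ((4.0, 13.0), (13.0, 45.0))

DEFAULT_FEATURE_NAMES = (
    "mean",
    "rms",
    "skewness",
    "fluctuation_index",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "shannon_entropy",
    "mean_teager_energy",
    "rel_power_4_13",
    "rel_power_13_45",
    "wavelet_energy_entropy",
)


@dataclass
class FeatureConfig:
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS
    entropy_bins: int = 16
    wavelet: WaveletSpec = field(default_factory=WaveletSpec)
    standardize: bool = True


@dataclass
class FeatureMatrix:
    """Segments-by-features table with named columns and segment ids."""

    values: np.ndarray
    feature_names: list[str]
    segment_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature names")
        if self.values.shape[0] != len(self.segment_ids):
            raise ValueError("row count does not match segment ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.feature_names,
            index=pd.Index(self.segment_ids, name="id"),
        )


def basic_stats(segment: np.ndarray) -> tuple[float, float, float]:
    """Arithmetic mean, root mean square and sample skewness."""
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    mean = float(np.mean(x))
    rms = float(np.sqrt(np.mean(x**2)))
    if np.var(x) == 0.0:
        warnings.warn("zero-variance segment; skewness set to 0", stacklevel=2)
        return mean, rms, 0.0
    skew = float(stats.skew(x, bias=True))
    return mean, rms, skew


def hjorth(segment: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity (variance), mobility and complexity.

    Mobility is ``sqrt(var(dx)/var(x))`` with dx the first difference;
    complexity is the mobility of dx over the mobility of x.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var_x = float(np.var(x))
    if var_x == 0.0:
        warnings.warn("zero-variance segment; Hjorth set to 0", stacklevel=2)
        return 0.0, 0.0, 0.0
    dx = np.diff(x)
    ddx = np.diff(dx)
    var_dx = float(np.var(dx))
    var_ddx = float(np.var(ddx))
    mobility = np.sqrt(var_dx / var_x)
    if var_dx == 0.0:
        return var_x, float(mobility), 0.0
    complexity = np.sqrt(var_ddx / var_dx) / mobility
    return var_x, float(mobility), float(complexity)


def shannon_entropy(segment: np.ndarray, bins: int = 16) -> float:
    """Histogram Shannon entropy in nats over equal-width amplitude bins."""
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = np.asarray(segment, dtype=float)
    if np.ptp(x) == 0.0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


def mean_teager_energy(segment: np.ndarray) -> float:
    """Mean Teager energy ``mean(x[n]^2 - x[n-1]*x[n+1])`` over the interior."""
    x = np.asarray(segment, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(np.mean(psi))


def fluctuation_index(segment: np.ndarray) -> float:
    """Mean absolute first difference."""
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.mean(np.abs(np.diff(x))))


def spectral_features(
    segment: np.ndarray,
    fs: float,
    bands: tuple[tuple[float, float], ...] = DEFAULT_BANDS,
) -> np.ndarray:
    """Relative band powers plus the spectral peak frequency.

    Band powers come from periodogram integration normalized by total power;
    the returned vector is ``[rel_power(band_1), ..., peak_frequency]``.
    """
    x = np.asarray(segment, dtype=float)
    nyq = fs / 2
    for lo, hi in bands:
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band ({lo}, {hi}) must lie inside (0, {nyq})")
    f, p = sps.periodogram(x, fs=fs)
    total = float(np.sum(p))
    if total == 0.0:
        warnings.warn("degenerate signal; spectral features set to 0", stacklevel=2)
        return np.zeros(len(bands) + 1)
    rel = [float(np.sum(p[(f >= lo) & (f < hi)])) / total for lo, hi in bands]
    peak = float(f[np.argmax(p)])
    return np.array(rel + [peak])


def wavelet_subband_features(
    segment: np.ndarray, spec: WaveletSpec | None = None
) -> np.ndarray:
    """Relative energy per decomposition level plus wavelet energy entropy.

    The returned vector is ``[e_approx, e_detail_L, ..., e_detail_1, H]``
    where H = -sum(e_i ln e_i) over the relative level energies.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(segment, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(spec.name).dec_len)
    levels = min(spec.levels, max_level)
    coeffs = pywt.wavedec(x, spec.name, level=levels)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    if total == 0.0:
        return np.zeros(energies.size + 1)
    rel = energies / total
    nz = rel[rel > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    return np.concatenate([rel, [entropy]])


def _feature_row(seg: SignalSegment, cfg: FeatureConfig) -> np.ndarray:
    x = seg.samples
    mean, rms, skew = basic_stats(x)
    act, mob, comp = hjorth(x)
    rel_powers = spectral_features(x, seg.fs, cfg.bands)[: len(cfg.bands)]
    wave = wavelet_subband_features(x, cfg.wavelet)
    return np.array(
        [
            mean,
            rms,
            skew,
            fluctuation_index(x),
            act,
            mob,
            comp,
            shannon_entropy(x, cfg.entropy_bins),
            mean_teager_energy(x),
            *rel_powers,
            wave[-1],
        ]
    )


def extract_feature_matrix(
    segments: list[SignalSegment], config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Extract the 12-feature matrix, optionally z-scored per column.

    Standardization (the default) puts mixed-unit features on a common
    scale before the embedding stage; columns with zero spread are left
    centered instead of divided.
    """
    cfg = config or FeatureConfig()
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    rows = []
    for seg in segments:
        row = _feature_row(seg, cfg)
        if not np.all(np.isfinite(row)):
            bad = DEFAULT_FEATURE_NAMES[int(np.argmax(~np.isfinite(row)))]
            raise ValueError(
                f"non-finite feature {bad!r} for segment {seg.id!r}"
            )
        rows.append(row)
    values = np.vstack(rows)
    standardized = False
    if cfg.standardize:
        mu = values.mean(axis=0)
        sd = values.std(axis=0)
        sd[sd == 0.0] = 1.0
        values = (values - mu) / sd
        standardized = True
    return FeatureMatrix(
        values=values,
        feature_names=list(DEFAULT_FEATURE_NAMES),
        segment_ids=[s.id for s in segments],
        standardized=standardized,
    )
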