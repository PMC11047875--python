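"""Synthetic EEG-like segment generator.

Emulates the geometry of short single-channel epileptic-EEG recordings:
fixed-rate, fixed-length segments drawn from a small number of latent
stages.  Each stage is band-limited colored noise in a characteristic
rhythm band plus stage-specific transients (sharp interictal-like spikes,
or slow high-amplitude ictal-like discharges).  Amplitudes are unitless
but documented as µV-like; no clinical calibration is claimed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .segment import LabeledDataset, SignalSegment

__all__ = [
    "ClassSpec",
    "SynthConfig",
    "generate_dataset",
    "generate_segment",
    "add_noise",
    "DEFAULT_CLASSES",
]


@dataclass(frozen=True)
class ClassSpec:
    """Spectral template for one latent stage.

    band : rhythm band (lo, hi) in Hz for the colored-noise carrier
    amplitude : RMS scale of the carrier, µV-like
    spike_rate : expected transients per second (Poisson)
    spike_amplitude : peak scale of each transient
    spike_width_s : half-width of the Mexican-hat transient in seconds
    """

    name: str
    band: tuple[float, float]
    amplitude: float = 1.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    spike_width_s: float = 0.02


#: Three stage templates: alpha-band background, background plus sparse sharp
#: transients (interictal-like), and high-amplitude ~3 Hz rhythmic discharges
#: (ictal-like).
DEFAULT_CLASSES: tuple[ClassSpec, ...] = (
    ClassSpec(name="background", band=(8.0, 13.0), amplitude=1.0),
    ClassSpec(
        name="interictal",
        band=(8.0, 13.0),
        amplitude=1.0,
        spike_rate=1.5,
        spike_amplitude=8.0,
        spike_width_s=0.02,
    ),
    ClassSpec(
        name="ictal",
        band=(2.0, 4.5),
        amplitude=3.0,
        spike_rate=3.0,
        spike_amplitude=5.0,
        spike_width_s=0.06,
    ),
)


@dataclass
class SynthConfig:
    """Dataset geometry and stage templates.

    Defaults mirror a typical segmented scalp-EEG protocol: 50 segments per
    stage, 5.12 s per segment at 200 Hz (1024 samples), three stages.
    """

    n_per_class: int = 50
    fs: float = 200.0
    duration_s: float = 5.12
    classes: tuple[ClassSpec, ...] = DEFAULT_CLASSES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 classes")
        n = self.fs * self.duration_s
        if abs(n - round(n)) > 1e-9 or round(n) < 64:
            raise ValueError(
                "fs * duration_s must be an integer sample count >= 64"
            )
        nyq = self.fs / 2
        for spec in self.classes:
            lo, hi = spec.band
            if not (0 < lo < hi < nyq):
                raise ValueError(
                    f"class {spec.name!r} band {spec.band} must lie in (0, {nyq})"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))


def _mexican_hat(width_samples: int) -> np.ndarray:
    """Mexican-hat (Ricker) pulse with unit peak, support ~8 sigma."""
    sigma = width_samples / 2.0
    t = np.arange(-4 * sigma, 4 * sigma + 1)
    x = (t / sigma) ** 2
    return (1.0 - x) * np.exp(-x / 2.0)


def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS colored noise restricted to ``band`` (zero-phase Butterworth)."""
    lo, hi = band
    white = rng.standard_normal(n + 512)  # pad to damp filter transients
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    colored = sps.sosfiltfilt(sos, white)[256 : 256 + n]
    rms = np.sqrt(np.mean(colored**2))
    return colored / rms


def generate_segment(
    spec: ClassSpec, fs: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """One segment following a stage template; deterministic given ``rng``."""
    x = spec.amplitude * _bandlimited_noise(n_samples, fs, spec.band, rng)
    if spec.spike_rate > 0 and spec.spike_amplitude > 0:
        duration = n_samples / fs
        n_spikes = rng.poisson(spec.spike_rate * duration)
        pulse = _mexican_hat(max(2, int(round(spec.spike_width_s * fs))))
        half = pulse.size // 2
        for _ in range(n_spikes):
            center = int(rng.integers(0, n_samples))
            amp = spec.spike_amplitude * rng.uniform(0.7, 1.3)
            lo = max(0, center - half)
            hi = min(n_samples, center + half + 1)
            x[lo:hi] += amp * pulse[lo - center + half : hi - center + half]
    return x


def generate_dataset(cfg: SynthConfig) -> LabeledDataset:
    """Generate ``n_per_class`` segments for every stage template.

    Per-segment random streams are spawned from the root seed, so the
    dataset is byte-identical across runs with the same configuration.
    """
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(len(cfg.classes) * cfg.n_per_class)
    segments: list[SignalSegment] = []
    labels: list[int] = []
    idx = 0
    for k, spec in enumerate(cfg.classes):
        for j in range(cfg.n_per_class):
            rng = np.random.default_rng(streams[idx])
            samples = generate_segment(spec, cfg.fs, cfg.n_samples, rng)
            segments.append(
                SignalSegment(
                    samples=samples,
                    fs=cfg.fs,
                    id=f"{spec.name}_{j:03d}",
                    stage_label=k,
                )
            )
            labels.append(k)
            idx += 1
    return LabeledDataset(segments=segments, labels=np.asarray(labels))


def add_noise(
    signal: np.ndarray, snr_db: float, seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """Add white Gaussian noise at an exact signal-to-noise ratio.

    The noise realization is rescaled so that
    ``10*log10(sum(x**2) / sum(e**2))`` equals ``snr_db`` up to floating-point
    rounding.  ``snr_db = inf`` returns the signal unchanged.
    """
    x = np.asarray(signal, dtype=float)
    power = float(np.sum(x**2))
    if power == 0.0:
        raise ValueError("cannot set an SNR against a zero-power signal")
    if math.isinf(snr_db) and snr_db > 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(x.size)
    noise_power = float(np.sum(noise**2))
    target_noise_power = power / (10.0 ** (snr_db / 10.0))
    return x + noise * math.sqrt(target_noise_power / noise_power)


def band_power_ratio(
    samples: np.ndarray, fs: float, band: tuple[float, float]
) -> float:
    """Mean in-band power density over mean out-of-band density (periodogram).

    Used to assert that generated classes are spectrally separable.
    """
    f, p = sps.periodogram(samples, fs=fs)
    inside = (f >= band[0]) & (f <= band[1])
    in_density = p[inside].mean()
    out_density = p[~inside & (f > 0)].mean()
    return float(in_density / out_density)
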