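"""Core signal container shared by every pipeline stage."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MIN_SEGMENT_LENGTH = 64


@dataclass
class SignalSegment:
    """One fixed-rate EEG time series.

    Parameters
    ----------
    samples : ndarray
        Amplitude values in µV-like units.
    fs : float
        Sampling rate in Hz.
    id : str
        Stable identifier used in file manifests and feature tables.
    stage_label : int or None
        Optional seizure-stage class (e.g. 0 = background, 1 = interictal-like,
        2 = ictal-like). ``None`` for unlabeled data.
    """

    samples: np.ndarray
    fs: float
    id: str = "seg"
    stage_label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < MIN_SEGMENT_LENGTH:
            raise ValueError(
                f"segment {self.id!r} has {self.samples.size} samples; "
                f"need at least {MIN_SEGMENT_LENGTH}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"segment {self.id!r} contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class LabeledDataset:
    """Segments with integer class labels, aligned by position."""

    segments: list[SignalSegment] = field(default_factory=list)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.segments) != self.labels.size:
            raise ValueError("segments and labels must have equal length")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0
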