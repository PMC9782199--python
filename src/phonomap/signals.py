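"""In-memory containers for multichannel PCG and ECG signals.

The phonocardiogram (PCG) is stored as a channels x samples float matrix with
a single sampling rate; the ECG is a single trace that optionally carries the
detected (or ground-truth) R-peak sample indices.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class MultichannelRecording:
    """Channels x samples matrix of heart-sound voltages.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        One row per sensor channel, in volts or normalized units.
    fs : float
        Sampling rate in Hz.
    channel_ids : list of int, optional
        Channel labels; defaults to 1..n_channels.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channel_ids:
            self.channel_ids = list(range(1, self.data.shape[0] + 1))
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray) -> "MultichannelRecording":
        """Copy of this recording with the sample matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class EcgTrace:
    """Single-channel ECG with optional R-peak annotations.

    ``r_peaks`` are sample indices into ``samples`` (strictly increasing).
    """

    samples: np.ndarray
    fs: float
    r_peaks: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.r_peaks is not None:
            self.r_peaks = np.asarray(self.r_peaks, dtype=int).ravel()
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if self.r_peaks.size and self.r_peaks[-1] >= self.samples.size:
                raise ValueError("r_peaks out of range")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs
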