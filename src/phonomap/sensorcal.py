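"""Sensor and analogue front-end characterisation.

Closed-form RC high-pass cut-offs and amplifier gain chains for the sensor
electronics, plus the bench-test statistics: PSD-based centre-frequency
estimation, amplitude/frequency consistency difference rates between two
sensors, and signal-to-noise ratio in dB.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError

__all__ = [
    "RCFilterSpec",
    "GainChain",
    "ConsistencyResult",
    "SnrResult",
    "rc_highpass_cutoff",
    "gain_chain_db",
    "snr_db",
    "difference_rates",
    "estimate_center_frequency",
    "consistency_result",
]


@dataclass
class RCFilterSpec:
    """First-order RC high-pass: capacitance (F) and resistance (ohm)."""

    capacitance: float
    resistance: float

    def __post_init__(self) -> None:
        if self.capacitance <= 0 or self.resistance <= 0:
            raise ValueError("capacitance and resistance must be positive")


@dataclass
class GainChain:
    """Cascade of amplifier stages, each specified in dB."""

    stage_gains_db: list[float]

    def __post_init__(self) -> None:
        if not self.stage_gains_db:
            raise ValueError("gain chain must have at least one stage")
        if not np.all(np.isfinite(self.stage_gains_db)):
            raise ValueError("stage gains must be finite")


@dataclass
class ConsistencyResult:
    """Two-sensor consistency at one test frequency j.

    delta_v = |V_A - V_B| / V_B and delta_f = |f_A - f_B| / f_B are the
    dimensionless amplitude and frequency difference rates.
    """

    test_freq: float
    v_a: float
    v_b: float
    f_a: float
    f_b: float
    delta_v: float
    delta_f: float


@dataclass
class SnrResult:
    p_signal: float
    p_noise: float
    snr_db: float


def rc_highpass_cutoff(spec: RCFilterSpec) -> float:
    """Cut-off frequency f_c = 1 / (2 pi R C) in Hz."""
    return 1.0 / (2.0 * np.pi * spec.capacitance * spec.resistance)


def gain_chain_db(chain: GainChain) -> float:
    """Overall gain of a cascade: the sum of the stage gains in dB."""
    return float(np.sum(chain.stage_gains_db))


def snr_db(p_signal: float, p_noise: float) -> float:
    """Signal-to-noise ratio 10 log10(P1 / P2) in dB."""
    if p_signal <= 0 or p_noise <= 0:
        raise ValueError("powers must be positive")
    return 10.0 * np.log10(p_signal / p_noise)


def difference_rates(v_a: float, v_b: float, f_a: float, f_b: float
                     ) -> tuple[float, float]:
    """Amplitude and frequency difference rates between sensors A and B."""
    if v_b == 0 or f_b == 0:
        raise ValueError("reference amplitude/frequency must be non-zero")
    return abs(v_a - v_b) / abs(v_b), abs(f_a - f_b) / abs(f_b)


def estimate_center_frequency(samples: np.ndarray, fs: float,
                              segment_seconds: float = 2.0) -> float:
    """Centre frequency of a narrowband signal from its Welch PSD.

    The PSD is averaged over Hann-windowed segments (default 2 s, 50%
    overlap, mirroring a 40 s bench sweep at 2 kHz) and the peak bin is
    refined by parabolic interpolation on log power.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2 or np.allclose(x, x[0]):
        raise DegenerateInputError("constant signal has no spectral peak")
    nperseg = min(x.size, int(round(segment_seconds * fs)))
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2)
    peak = int(np.argmax(psd[1:])) + 1  # exclude the DC bin
    if 1 <= peak < psd.size - 1 and psd[peak - 1] > 0 and psd[peak + 1] > 0:
        la, lb, lc = np.log(psd[peak - 1: peak + 2])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(freqs[peak] + delta * (freqs[1] - freqs[0]))


def _tone_amplitude(x: np.ndarray) -> float:
    """Amplitude of a sinusoid from its mean power (A = sqrt(2 P))."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    return float(np.sqrt(2.0 * np.mean(x ** 2)))


def consistency_result(a: np.ndarray, b: np.ndarray, fs: float,
                       test_freq: float) -> ConsistencyResult:
    """Consistency statistics for one played tone recorded by sensors A and B."""
    v_a, v_b = _tone_amplitude(a), _tone_amplitude(b)
    f_a = estimate_center_frequency(a, fs)
    f_b = estimate_center_frequency(b, fs)
    dv, df = difference_rates(v_a, v_b, f_a, f_b)
    return ConsistencyResult(test_freq=test_freq, v_a=v_a, v_b=v_b,
                             f_a=f_a, f_b=f_b, delta_v=dv, delta_f=df)
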