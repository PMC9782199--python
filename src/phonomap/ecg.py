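"""ECG conditioning and R-wave detection.

The ECG anchors the cardiac cycle: R-peaks detected with the Pan-Tompkins
algorithm provide the time references against which S1/S2 map frames are
indexed.  Conditioning follows a down-filter-up scheme: the trace is
resampled to 200 Hz (the algorithm's native design rate), band-passed at
0.5-40 Hz with a zero-phase Butterworth filter, and resampled to 10 kHz to
match the PCG timebase.
"""
from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signals import EcgTrace

__all__ = ["preprocess_ecg", "detect_r_peaks", "segment_cycles"]

#: Intermediate processing / detection rate (Hz).
DETECTION_FS = 200.0
#: Output rate matching the PCG timebase (Hz).
OUTPUT_FS = 10_000.0
#: Pan-Tompkins refractory period (s): no two QRS closer than this.
REFRACTORY_S = 0.200
#: Moving-window-integration length (s).
MWI_WINDOW_S = 0.150


def _resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased rational resampling."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                             frac.denominator)


def preprocess_ecg(trace: EcgTrace, low_hz: float = 0.5, high_hz: float = 40.0,
                   intermediate_fs: float = DETECTION_FS,
                   output_fs: float = OUTPUT_FS) -> EcgTrace:
    """Resample to 200 Hz, band-pass 0.5-40 Hz (zero phase), resample to 10 kHz.

    The 0.5 Hz corner removes baseline wander and DC, the 40 Hz corner the
    mains/EMG band; duration is preserved to within one sample.
    """
    if trace.fs < 2 * intermediate_fs:
        raise ValueError(f"input rate {trace.fs} Hz must be >= "
                         f"{2 * intermediate_fs} Hz")
    x = _resample(trace.samples, trace.fs, intermediate_fs)
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass",
                     fs=intermediate_fs, output="sos")
    if x.size <= 50:
        raise ValueError("trace shorter than the filter warm-up")
    x = sps.sosfiltfilt(sos, x)
    y = _resample(x, intermediate_fs, output_fs)
    return EcgTrace(samples=y, fs=output_fs)


def _pan_tompkins_200hz(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection on a trace at ~200 Hz.

    Stages: 5-15 Hz band-pass, five-point derivative, squaring, 150 ms
    moving-window integration, then adaptive dual thresholds with a 200 ms
    refractory period and RR-based search-back.  Returns QRS fiducial
    indices on the band-passed trace.
    """
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8.0),
                        mode="same")
    sq = deriv ** 2
    win = max(1, int(round(MWI_WINDOW_S * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")
    if not np.any(mwi > 0):
        return np.zeros(0, dtype=int)

    refractory = int(round(REFRACTORY_S * fs))
    peaks, _ = sps.find_peaks(mwi, distance=refractory)
    if peaks.size == 0:
        return np.zeros(0, dtype=int)

    # Threshold initialisation from the first two seconds.
    head = mwi[: int(2 * fs)] if mwi.size > int(2 * fs) else mwi
    spki = 0.25 * float(head.max())
    npki = 0.5 * float(np.mean(head))
    qrs: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    for p in peaks:
        if mwi[p] > threshold():
            if qrs and p - qrs[-1] < refractory:
                continue
            # Search-back: a missed beat leaves an overlong RR interval.
            if qrs and rr_history:
                rr_avg = float(np.mean(rr_history[-8:]))
                if p - qrs[-1] > 1.66 * rr_avg:
                    gap = peaks[(peaks > qrs[-1] + refractory) & (peaks < p)]
                    if gap.size:
                        cand = gap[np.argmax(mwi[gap])]
                        if mwi[cand] > 0.5 * threshold():
                            rr_history.append(cand - qrs[-1])
                            qrs.append(int(cand))
                            spki = 0.25 * float(mwi[cand]) + 0.75 * spki
            if qrs:
                rr_history.append(p - qrs[-1])
            qrs.append(int(p))
            spki = 0.125 * float(mwi[p]) + 0.875 * spki
        else:
            npki = 0.125 * float(mwi[p]) + 0.875 * npki

    # MWI maxima trail the R-wave; snap each fiducial to the dominant
    # excursion of the band-passed ECG in the preceding integration window.
    out = []
    for p in qrs:
        lo = max(0, p - win)
        seg = np.abs(bp[lo: p + 1])
        out.append(lo + int(np.argmax(seg)))
    return np.unique(np.asarray(out, dtype=int))


def detect_r_peaks(trace: EcgTrace, detection_fs: float = DETECTION_FS
                   ) -> np.ndarray:
    """Detect R-peaks with Pan-Tompkins; indices at the trace's own rate.

    Detection runs at 200 Hz; each detection is then refined to the local
    maximum of the trace at its native rate within +-12.5 ms.  A flat or
    pure-noise trace yields an empty result rather than an exception.
    """
    x = trace.samples
    if x.size == 0 or np.allclose(x, x.flat[0]):
        return np.zeros(0, dtype=int)
    xd = _resample(x, trace.fs, detection_fs)
    rough = _pan_tompkins_200hz(xd, detection_fs)
    if rough.size == 0:
        return rough
    scale = trace.fs / detection_fs
    half = int(round(0.0125 * trace.fs))
    refined = []
    for r in rough:
        c = int(round(r * scale))
        lo, hi = max(0, c - half), min(x.size, c + half + 1)
        if lo >= hi:
            continue
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(np.asarray(refined, dtype=int))
    # Enforce the refractory spacing after refinement.
    keep = [int(refined[0])]
    min_gap = REFRACTORY_S * trace.fs
    for r in refined[1:]:
        if r - keep[-1] >= min_gap:
            keep.append(int(r))
    return np.asarray(keep, dtype=int)


def segment_cycles(r_peaks: np.ndarray, n_samples: int
                   ) -> list[tuple[int, int]]:
    """Consecutive R-to-R half-open intervals [r_k, r_{k+1}).

    Leading and trailing partial cycles are excluded; fewer than two peaks
    give an empty list.
    """
    r = np.asarray(r_peaks, dtype=int)
    if np.any(np.diff(r) <= 0):
        raise ValueError("r_peaks must be sorted strictly increasing")
    r = r[(r >= 0) & (r < n_samples)]
    return [(int(a), int(b)) for a, b in zip(r[:-1], r[1:])]
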