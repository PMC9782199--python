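"""File I/O: multichannel WAV (float32), CSV/NPY matrices, images.

WAV files are written as 32-bit float, one column per channel, which is
lossless for the pipeline's normalised dynamic range.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .signals import EcgTrace, MultichannelRecording


def write_recording_wav(path: str | Path, rec: MultichannelRecording) -> None:
    wavfile.write(str(path), int(rec.fs), rec.data.T.astype(np.float32))


def read_recording_wav(path: str | Path) -> MultichannelRecording:
    fs, data = wavfile.read(str(path))
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] > data.shape[1]:
        data = data.T
    return MultichannelRecording(data=data, fs=float(fs))


def write_ecg_wav(path: str | Path, trace: EcgTrace) -> None:
    wavfile.write(str(path), int(trace.fs), trace.samples.astype(np.float32))


def read_ecg_wav(path: str | Path) -> EcgTrace:
    fs, data = wavfile.read(str(path))
    return EcgTrace(samples=np.asarray(data, dtype=float).ravel(), fs=float(fs))


def load_recording(path: str | Path, fs: float | None = None
                   ) -> MultichannelRecording:
    """Load a channels x samples matrix from WAV, CSV or NPY by suffix."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".wav":
        return read_recording_wav(p)
    if suffix == ".npy":
        data = np.load(p)
    elif suffix in (".csv", ".txt"):
        data = np.loadtxt(p, delimiter=",")
    else:
        raise ValueError(f"unsupported recording format: {suffix}")
    if fs is None:
        raise ValueError("fs is required for CSV/NPY input")
    return MultichannelRecording(data=np.atleast_2d(data), fs=fs)


def save_recording(path: str | Path, rec: MultichannelRecording) -> None:
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".wav":
        write_recording_wav(p, rec)
    elif suffix == ".npy":
        np.save(p, rec.data)
    elif suffix in (".csv", ".txt"):
        np.savetxt(p, rec.data, delimiter=",")
    else:
        raise ValueError(f"unsupported recording format: {suffix}")


def read_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio
    return np.asarray(iio.imread(str(path)))


def write_image(path: str | Path, image: np.ndarray) -> None:
    import imageio.v3 as iio
    iio.imwrite(str(path), np.asarray(image))
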