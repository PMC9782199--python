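"""Synthetic multichannel PCG / ECG recordings and marker images.

These generators produce fully characterised inputs for every pipeline stage:
a rectilinear sensor grid, a 72-channel heart-sound array whose S1/S2 bursts
radiate from virtual point sources with exponential spatial decay, a
synchronised ECG whose R-waves precede S1 by a known delay, and raster images
bearing coloured disc markers for the registration stage.  Every generator is
deterministic under a fixed seed.

The burst model is a Gabor atom (Gaussian-windowed sinusoid): band-limited,
with centre frequency and bandwidth directly controllable, which matches the
20-200 Hz band that dominates normal heart sounds.  Spatial attenuation is
exponential in Euclidean pixel distance — a monotone gradient stand-in, not a
thoracic propagation model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import SensorLayout
from .signals import EcgTrace, MultichannelRecording

__all__ = [
    "BeatSchedule",
    "SourceSpec",
    "generate_sensor_layout",
    "generate_pcg_array",
    "generate_ecg",
    "render_marker_image",
    "default_landmarks",
    "similarity_map",
    "make_registration_scene",
    "MARKER_COLORS",
]


@dataclass
class BeatSchedule:
    """Cardiac timing: R-wave times plus the S1/S2 onset delays.

    ``s1_delay`` and ``s2_delay`` are the intervals (s) from each R-wave to
    the centre of the S1 and S2 bursts; physiologically S1 follows the R-wave
    within a few tens of milliseconds and S2 follows roughly 0.3 s later.
    """

    beat_times: list[float]
    s1_delay: float = 0.04
    s2_delay: float = 0.34

    def __post_init__(self) -> None:
        times = np.asarray(self.beat_times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if not (0 < self.s1_delay < self.s2_delay):
            raise ValueError("need 0 < s1_delay < s2_delay")
        self.beat_times = list(times)

    @classmethod
    def regular(cls, n_beats: int, rr: float = 1.0, start: float = 0.5,
                s1_delay: float = 0.04, s2_delay: float = 0.34) -> "BeatSchedule":
        """Evenly spaced beats: ``n_beats`` at RR interval ``rr`` seconds."""
        times = [start + k * rr for k in range(n_beats)]
        return cls(times, s1_delay=s1_delay, s2_delay=s2_delay)


@dataclass
class SourceSpec:
    """Virtual acoustic point source in sensor-layout pixel coordinates.

    Each source emits one Gabor burst per S1 and per S2 instant; channel
    amplitudes decay as ``exp(-distance / decay_length)``.  ``s2_gain``
    scales the S2 burst relative to S1 (S2 is normally the quieter sound).
    """

    position: tuple[float, float]
    center_freq: float = 60.0
    bandwidth: float = 25.0
    amplitude: float = 1.0
    decay_length: float = 120.0
    s2_gain: float = 0.8
    s2_freq: float | None = None

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if not 20.0 <= self.center_freq <= 200.0:
            raise ValueError("center_freq outside the realistic 20-200 Hz band")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def generate_sensor_layout(n_rows: int, n_cols: int, spacing: float,
                           origin: tuple[float, float] = (0.0, 0.0)) -> SensorLayout:
    """Regular ``n_rows x n_cols`` sensor grid, channel ids 1..n row-major."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be at least 1x1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    ox, oy = origin
    coords = [(ox + c * spacing, oy + r * spacing)
              for r in range(n_rows) for c in range(n_cols)]
    return SensorLayout(coords=np.asarray(coords, dtype=float))


def _gabor(t: np.ndarray, center: float, freq: float, bandwidth: float) -> np.ndarray:
    """Gaussian-windowed tone burst centred at ``center`` seconds.

    Cosine phase: the oscillation extremum coincides with the envelope peak,
    so the burst centre is the sample of maximal amplitude.
    """
    sigma = 1.0 / (2.0 * np.pi * bandwidth)
    tt = t - center
    return np.exp(-0.5 * (tt / sigma) ** 2) * np.cos(2.0 * np.pi * freq * tt)


def generate_pcg_array(layout: SensorLayout, schedule: BeatSchedule,
                       sources: list[SourceSpec], fs: float = 10_000.0,
                       noise_sd: float = 0.0, seed: int = 0,
                       duration: float | None = None) -> MultichannelRecording:
    """Synthesize the multichannel heart-sound array.

    Each channel is the sum over sources of S1/S2 Gabor bursts, scaled by
    ``exp(-d / decay_length)`` where ``d`` is the sensor-to-source pixel
    distance, plus white Gaussian noise of standard deviation ``noise_sd``
    drawn per channel in channel order from one seeded generator.
    """
    if not sources:
        raise ValueError("at least one source is required")
    fmax = max(max(s.center_freq, s.s2_freq or 0.0) for s in sources)
    if fs < 2.0 * fmax:
        raise ValueError(f"fs={fs} below Nyquist rate for a {fmax} Hz source")
    if duration is None:
        last = (schedule.beat_times[-1] + schedule.s2_delay + 0.5
                if schedule.beat_times else 1.0)
        duration = last
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    data = np.zeros((len(layout), n))
    for src in sources:
        d = np.hypot(layout.x - src.position[0], layout.y - src.position[1])
        gains = src.amplitude * np.exp(-d / src.decay_length)
        burst = np.zeros(n)
        for bt in schedule.beat_times:
            burst += _gabor(t, bt + schedule.s1_delay, src.center_freq,
                            src.bandwidth)
            burst += src.s2_gain * _gabor(t, bt + schedule.s2_delay,
                                          src.s2_freq or src.center_freq,
                                          src.bandwidth)
        data += gains[:, None] * burst[None, :]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        for ch in range(len(layout)):
            data[ch] += rng.normal(0.0, noise_sd, size=n)
    return MultichannelRecording(data=data, fs=fs,
                                 channel_ids=list(layout.channel_ids))


# PQRST wave amplitudes (relative to R), centers (s from R) and widths (s).
_ECG_WAVES = (
    (0.15, -0.17, 0.025),   # P
    (-0.08, -0.025, 0.008), # Q
    (1.00, 0.0, 0.007),     # R
    (-0.18, 0.025, 0.009),  # S
    (0.30, 0.19, 0.045),    # T
)


def generate_ecg(schedule: BeatSchedule, fs: float = 10_000.0,
                 noise_sd: float = 0.0, seed: int = 0,
                 duration: float | None = None) -> EcgTrace:
    """Synthetic PQRST-like ECG with known R-peak sample indices.

    Each wave is a Gaussian bump; the R spike is tall and narrow so it
    dominates the trace.  The returned trace carries the ground-truth R
    indices (``round(beat_time * fs)``).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not schedule.beat_times:
        return EcgTrace(samples=np.zeros(0), fs=fs, r_peaks=np.zeros(0, dtype=int))
    if duration is None:
        duration = schedule.beat_times[-1] + 0.6
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for bt in schedule.beat_times:
        for amp, center, width in _ECG_WAVES:
            x += amp * np.exp(-0.5 * ((t - bt - center) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=n)
    r = np.round(np.asarray(schedule.beat_times) * fs).astype(int)
    r = r[r < n]
    return EcgTrace(samples=x, fs=fs, r_peaks=r)


def default_landmarks(layout: SensorLayout, margin: float = 55.0) -> np.ndarray:
    """Four registration-landmark positions framing a sensor layout.

    Rows follow the anatomical ordering used throughout the registration
    stage: sternoclavicular joint (top centre), right 10th rib (bottom,
    image-left of centre), right 6th rib (image left), left 6th rib (image
    right).  Anatomical right appears on the image left in a frontal view.
    """
    x0, x1 = float(layout.x.min()), float(layout.x.max())
    y0, y1 = float(layout.y.min()), float(layout.y.max())
    cx = 0.5 * (x0 + x1)
    y6 = y0 + 0.6 * (y1 - y0)
    return np.array([
        [cx, y0 - margin],                      # sternoclavicular joint
        [x0 + 0.3 * (x1 - x0), y1 + margin],    # right 10th rib
        [x0 - margin, y6],                      # right 6th rib
        [x1 + margin, y6],                      # left 6th rib
    ])


def similarity_map(points: np.ndarray, rotation_deg: float, scale: float,
                   translation: tuple[float, float]) -> np.ndarray:
    """Apply a planar similarity (rotate about origin, scale, translate)."""
    a = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return scale * (pts @ rot.T) + np.asarray(translation, dtype=float)


def make_registration_scene(layout: SensorLayout, rotation_deg: float = 8.0,
                            scale: float = 1.25,
                            translation: tuple[float, float] = (40.0, 30.0),
                            sensor_radius: float = 7.0,
                            landmark_radius: float = 10.0) -> dict:
    """Chest-photo / skeleton-image pair with known ground truth.

    The chest photo carries green sensor discs at the layout positions and
    red landmark discs framing them; the skeleton image carries red landmark
    discs at the positions of the chest landmarks pushed through a known
    similarity transform.  The returned dict holds both images, the chest
    and skeleton landmark coordinates, and the ground-truth sensor positions
    in skeleton-image pixels (in the layout's channel order).
    """
    chest_lm = default_landmarks(layout)
    margin = landmark_radius + 6.0
    all_chest = np.vstack([layout.coords, chest_lm])
    shift = np.maximum(margin - all_chest.min(axis=0), 0.0)
    chest_pts = layout.coords + shift
    chest_lm = chest_lm + shift
    extent = np.vstack([chest_pts, chest_lm]).max(axis=0) + margin
    chest_img = render_marker_image(
        int(np.ceil(extent[0])) + 1, int(np.ceil(extent[1])) + 1,
        [((x, y), sensor_radius, "green") for x, y in chest_pts]
        + [((x, y), landmark_radius, "red") for x, y in chest_lm])

    skel_lm = similarity_map(chest_lm, rotation_deg, scale, translation)
    skel_sensors = similarity_map(chest_pts, rotation_deg, scale, translation)
    lo = np.vstack([skel_lm, skel_sensors]).min(axis=0)
    offset = np.maximum(margin - lo, 0.0)
    skel_lm = skel_lm + offset
    skel_sensors = skel_sensors + offset
    hi = np.vstack([skel_lm, skel_sensors]).max(axis=0) + margin
    skel_img = render_marker_image(
        int(np.ceil(hi[0])) + 1, int(np.ceil(hi[1])) + 1,
        [((x, y), landmark_radius, "red") for x, y in skel_lm])
    return {
        "chest_image": chest_img,
        "skeleton_image": skel_img,
        "chest_sensors": chest_pts,
        "chest_landmarks": chest_lm,
        "skeleton_landmarks": skel_lm,
        "skeleton_sensors": skel_sensors,
    }


#: Saturated marker colours (RGB in [0, 1]) suited to HSV thresholding.
MARKER_COLORS = {
    "red": (0.86, 0.10, 0.10),
    "green": (0.10, 0.62, 0.22),
    "blue": (0.12, 0.25, 0.82),
}

_BACKGROUND = (0.96, 0.96, 0.93)


def render_marker_image(width: int, height: int,
                        discs: list[tuple[tuple[float, float], float, str]]
                        ) -> np.ndarray:
    """Render coloured discs on a near-white background.

    ``discs`` is a list of ((cx, cy), radius, color_name).  Discs are drawn
    with analytic anti-aliasing (one-pixel soft edge) so that sub-pixel
    centres survive a round-trip through marker extraction.  Returns an RGB
    uint8 image of shape (height, width, 3).
    """
    img = np.empty((height, width, 3), dtype=float)
    img[:] = _BACKGROUND
    yy, xx = np.mgrid[0:height, 0:width]
    for (cx, cy), radius, color_name in discs:
        if radius <= 0:
            raise ValueError("disc radius must be positive")
        if (cx - radius < 0 or cx + radius > width - 1
                or cy - radius < 0 or cy + radius > height - 1):
            raise ValueError(f"disc at ({cx}, {cy}) r={radius} out of bounds")
        color = np.asarray(MARKER_COLORS[color_name])
        dist = np.hypot(xx - cx, yy - cy)
        alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)[:, :, None]
        img = (1.0 - alpha) * img + alpha * color
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
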