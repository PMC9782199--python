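"""Cardiac acoustic maps: modulus fields interpolated over the chest image.

At each sample instant n the per-channel modulus e_i(n) = |s_i(n)| of the
preprocessed heart-sound ensemble, together with the registered sensor
coordinates, defines a scattered data set that is interpolated with a
piecewise-cubic C1 spline onto a pixel grid.  The interpolated modulus is
normalised by a maximum Em and mapped to hue by

    eps(n) = 240 * (1 - E(n)/Em)

so that zero modulus is blue (240 deg) and the maximum red (0 deg), with
saturation 1.0 and lightness 50% in HSL space; conversion to RGB produces
the rendered frame, alpha-composited over a skeleton background inside the
convex hull of the sensors.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator, RectBivariateSpline
from scipy.spatial import QhullError

from .layout import SensorLayout, as_grid
from .signals import MultichannelRecording

__all__ = [
    "ModulusSeries",
    "AcousticFrame",
    "ColorMapSpec",
    "RenderResult",
    "compute_modulus",
    "interpolate_frame",
    "modulus_to_hue",
    "hsl_to_rgb",
    "composite_frame",
    "render_sequence",
]


@dataclass
class ModulusSeries:
    """Channels x samples matrix of non-negative heart-sound moduli."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("moduli must be non-negative")


@dataclass
class AcousticFrame:
    """Interpolated modulus grid at one sample instant.

    ``values[j, i]`` is the modulus at pixel (grid_x[i], grid_y[j]);
    ``mask`` is True inside the convex hull of the sensors, where the
    interpolant is defined.
    """

    values: np.ndarray
    mask: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    sample_index: int | None = None


@dataclass
class ColorMapSpec:
    """Hue colormap: 240 deg (blue) at zero modulus down to 0 deg (red).

    ``em`` fixes the normalisation maximum; when None it is taken from the
    data according to ``em_scope``: 'global' (maximum over the rendered
    window, keeping colours comparable across frames) or 'per_frame'.
    """

    hue_max: float = 240.0
    saturation: float = 1.0
    lightness: float = 0.5
    em: float | None = None
    em_scope: str = "global"

    def __post_init__(self) -> None:
        if self.em is not None and self.em <= 0:
            raise ValueError("Em must be positive")
        if self.em_scope not in ("global", "per_frame", "recording"):
            raise ValueError("em_scope must be 'global', 'per_frame' or 'recording'")


@dataclass
class RenderResult:
    """Output of :func:`render_sequence`."""

    frames: list[np.ndarray]
    times: np.ndarray
    sample_indices: np.ndarray
    em: float
    acoustic_frames: list[AcousticFrame] = field(default_factory=list)


def compute_modulus(rec: MultichannelRecording) -> ModulusSeries:
    """Element-wise absolute value of the (preprocessed) ensemble."""
    return ModulusSeries(values=np.abs(rec.data), fs=rec.fs)


def interpolate_frame(layout: SensorLayout, moduli_at_n: np.ndarray,
                      grid_step: float = 1.0,
                      sample_index: int | None = None) -> AcousticFrame:
    """Interpolate scattered per-sensor moduli onto a pixel grid.

    Uses a tensor-product bicubic spline when the layout is a complete
    rectilinear grid, otherwise a Clough-Tocher piecewise-cubic C1
    interpolant on the Delaunay triangulation.  Both are exact at the sensor
    nodes; outside the sensor convex hull the mask is False and values 0.
    """
    vals = np.asarray(moduli_at_n, dtype=float).ravel()
    if vals.size != len(layout):
        raise ValueError("one modulus per sensor is required")
    if len(layout) < 3:
        raise ValueError("at least 3 non-collinear sensors are required")
    gx = np.arange(layout.x.min(), layout.x.max() + grid_step / 2, grid_step)
    gy = np.arange(layout.y.min(), layout.y.max() + grid_step / 2, grid_step)
    mx, my = np.meshgrid(gx, gy)

    grid = as_grid(layout)
    if grid is not None and len(grid[0]) >= 4 and len(grid[1]) >= 4:
        xs, ys, index = grid
        z = vals[index]
        spline = RectBivariateSpline(ys, xs, z, kx=3, ky=3, s=0)
        values = spline(gy, gx)
        mask = np.ones_like(values, dtype=bool)
    else:
        try:
            interp = CloughTocher2DInterpolator(layout.coords, vals,
                                                tol=1e-10, maxiter=1000)
        except QhullError as exc:
            raise ValueError(f"degenerate (collinear?) sensor layout: {exc}")
        values = interp(mx, my)
        mask = ~np.isnan(values)
        if not mask.any():
            raise ValueError("degenerate sensor layout: empty interpolation hull")
        values = np.where(mask, values, 0.0)
    return AcousticFrame(values=values, mask=mask, grid_x=gx, grid_y=gy,
                         sample_index=sample_index)


def modulus_to_hue(frame: AcousticFrame, spec: ColorMapSpec | None = None,
                   em: float | None = None) -> np.ndarray:
    """Hue field (degrees): eps = 240 * (1 - clip(E/Em, 0, 1)).

    Interpolation can overshoot the node values, so the normalised modulus
    is clipped to [0, 1] before the linear hue mapping.
    """
    spec = spec or ColorMapSpec()
    em = em if em is not None else spec.em
    if em is None:
        em = float(frame.values[frame.mask].max()) if frame.mask.any() else 0.0
    if em <= 0:
        raise ValueError("Em must be positive")
    eg = np.clip(frame.values / em, 0.0, 1.0)
    return spec.hue_max * (1.0 - eg)


def hsl_to_rgb(hue_deg: np.ndarray, saturation: float = 1.0,
               lightness: float = 0.5) -> np.ndarray:
    """Standard HSL -> RGB conversion, vectorised, 8-bit output.

    ``hue_deg`` in [0, 360), saturation and lightness in [0, 1]; returns a
    uint8 array with a trailing RGB axis.
    """
    h = np.asarray(hue_deg, dtype=float)
    if np.any((h < 0) | (h >= 360.0)):
        raise ValueError("hue must lie in [0, 360)")
    if not (0.0 <= saturation <= 1.0 and 0.0 <= lightness <= 1.0):
        raise ValueError("saturation and lightness must lie in [0, 1]")
    c = (1.0 - abs(2.0 * lightness - 1.0)) * saturation
    hp = h / 60.0
    x = c * (1.0 - np.abs(np.mod(hp, 2.0) - 1.0))
    zeros = np.zeros_like(h)
    sector = np.floor(hp).astype(int) % 6
    r = np.select([sector == 0, sector == 1, sector == 2, sector == 3,
                   sector == 4, sector == 5], [c, x, zeros, zeros, x, c])
    g = np.select([sector == 0, sector == 1, sector == 2, sector == 3,
                   sector == 4, sector == 5], [x, c, c, x, zeros, zeros])
    b = np.select([sector == 0, sector == 1, sector == 2, sector == 3,
                   sector == 4, sector == 5], [zeros, zeros, x, c, c, x])
    m = lightness - c / 2.0
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def composite_frame(frame: AcousticFrame, hue: np.ndarray,
                    background: np.ndarray, spec: ColorMapSpec,
                    alpha: float = 0.6) -> np.ndarray:
    """Alpha-blend the colour layer over the background inside the mask.

    The colour layer occupies the grid's pixel footprint in the background
    image; pixels outside the sensor hull show the background through.
    """
    bg = np.asarray(background)
    if bg.ndim == 2:
        bg = np.stack([bg] * 3, axis=-1)
    out = bg[..., :3].astype(float).copy()
    rgb = hsl_to_rgb(hue, spec.saturation, spec.lightness).astype(float)
    x0 = int(round(frame.grid_x[0]))
    y0 = int(round(frame.grid_y[0]))
    h, w = frame.values.shape
    ys = slice(y0, y0 + h)
    xs = slice(x0, x0 + w)
    region = out[ys, xs]
    m = frame.mask[: region.shape[0], : region.shape[1], None]
    blend = ((1.0 - alpha) * region
             + alpha * rgb[: region.shape[0], : region.shape[1]])
    out[ys, xs] = np.where(m, blend, region)
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def render_sequence(rec: MultichannelRecording, layout: SensorLayout,
                    background: np.ndarray, t_start: float, t_end: float,
                    frame_interval: float,
                    spec: ColorMapSpec | None = None,
                    grid_step: float = 1.0, alpha: float = 0.6,
                    out_dir: str | Path | None = None) -> RenderResult:
    """Render the time-resolved acoustic map over [t_start, t_end].

    One frame is produced every ``frame_interval`` seconds, endpoints
    inclusive (e.g. a 0.204-0.228 s window at 0.002 s yields 13 frames).
    With the default global Em scope, one normalisation maximum is taken
    over the whole rendered window so a given modulus maps to the same
    colour in every frame.  Frames are optionally written as numbered PNGs.
    """
    spec = spec or ColorMapSpec()
    if not (0 <= t_start <= t_end < rec.duration):
        raise ValueError("empty or out-of-range time window")
    bg = np.asarray(background)
    if (layout.x.min() < 0 or layout.y.min() < 0
            or layout.x.max() > bg.shape[1] - 1
            or layout.y.max() > bg.shape[0] - 1):
        raise ValueError("sensor layout exceeds background bounds")
    n_frames = int(np.floor((t_end - t_start) / frame_interval + 1e-9)) + 1
    times = t_start + frame_interval * np.arange(n_frames)
    indices = np.round(times * rec.fs).astype(int)
    moduli = compute_modulus(rec)

    aframes = [interpolate_frame(layout, moduli.values[:, n],
                                 grid_step=grid_step, sample_index=int(n))
               for n in indices]
    if spec.em is not None:
        em = spec.em
    elif spec.em_scope == "recording":
        em = float(moduli.values.max())
    else:
        em = float(max(f.values[f.mask].max() for f in aframes))
    if em <= 0:
        raise ValueError("window contains no signal: Em would be zero")

    frames = []
    for f in aframes:
        frame_em = (float(f.values[f.mask].max())
                    if spec.em_scope == "per_frame" else em)
        hue = modulus_to_hue(f, spec, em=max(frame_em, np.finfo(float).tiny))
        frames.append(composite_frame(f, hue, bg, spec, alpha=alpha))

    if out_dir is not None:
        import imageio.v3 as iio
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for k, img in enumerate(frames):
            iio.imwrite(out / f"frame_{k:04d}.png", img)
    return RenderResult(frames=frames, times=times, sample_indices=indices,
                        em=em, acoustic_frames=aframes)
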