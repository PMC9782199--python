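"""Sensor layouts: per-channel pixel coordinates on an image.

Coordinates follow the raster convention used throughout the package:
(x, y) = (column, row), origin at the top-left corner, y increasing downward.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class SensorLayout:
    """Pixel coordinates of sensor channels.

    Parameters
    ----------
    coords : ndarray, shape (n, 2)
        (x, y) pixel coordinates, one row per channel.
    channel_ids : list of int
        Channel labels, parallel to ``coords``; defaults to 1..n.
    """

    coords: np.ndarray
    channel_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        if not self.channel_ids:
            self.channel_ids = list(range(1, len(self.coords) + 1))
        if len(self.channel_ids) != len(self.coords):
            raise ValueError("channel_ids length must match coordinate count")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    def nearest_neighbor_distances(self) -> np.ndarray:
        """Distance from each sensor to its nearest other sensor."""
        d = np.linalg.norm(self.coords[:, None, :] - self.coords[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {str(c): [float(x), float(y)]
                   for c, (x, y) in zip(self.channel_ids, self.coords)}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SensorLayout":
        payload = json.loads(Path(path).read_text())
        ids = sorted(payload, key=int)
        coords = np.array([payload[c] for c in ids], dtype=float)
        return cls(coords=coords, channel_ids=[int(c) for c in ids])

    def to_csv(self, path: str | Path) -> None:
        lines = ["channel,x,y"] + [
            f"{c},{x!r},{y!r}" for c, (x, y) in zip(self.channel_ids, self.coords)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorLayout":
        rows = Path(path).read_text().strip().splitlines()[1:]
        ids, coords = [], []
        for row in rows:
            c, x, y = row.split(",")
            ids.append(int(c))
            coords.append((float(x), float(y)))
        return cls(coords=np.array(coords), channel_ids=ids)


def as_grid(layout: SensorLayout, tol: float = 1e-6):
    """Return (xs, ys, index_grid) if the layout is a complete rectilinear grid.

    ``index_grid[j, i]`` is the layout row at (xs[i], ys[j]); ``None`` when the
    coordinates do not tile a full grid (e.g. after a rotation).
    """
    xs = np.unique(np.round(layout.x / max(tol, 1e-12)) * max(tol, 1e-12))
    xs = _merge_close(np.sort(np.unique(layout.x)), tol)
    ys = _merge_close(np.sort(np.unique(layout.y)), tol)
    if len(xs) * len(ys) != len(layout):
        return None
    index = -np.ones((len(ys), len(xs)), dtype=int)
    for row, (x, y) in enumerate(layout.coords):
        i = int(np.argmin(np.abs(xs - x)))
        j = int(np.argmin(np.abs(ys - y)))
        if abs(xs[i] - x) > tol or abs(ys[j] - y) > tol or index[j, i] != -1:
            return None
        index[j, i] = row
    if (index < 0).any():
        return None
    return xs, ys, index


def _merge_close(values: np.ndarray, tol: float) -> np.ndarray:
    out = [values[0]]
    for v in values[1:]:
        if v - out[-1] > tol:
            out.append(v)
    return np.asarray(out)
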