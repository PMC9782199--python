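"""Sensor localisation by coloured-marker detection and landmark registration.

Sensors leave impressions on the chest that are marked with green discs on a
photograph; four red discs mark anatomical reference points (sternoclavicular
joint, right 10th rib, right and left 6th ribs).  The same four landmarks are
marked on a standard skeleton image.  Marker centres are recovered by HSV
colour thresholding followed by a Circle Hough transform; the chest-to-
skeleton mapping is a rotate / scale / translate chain estimated from the
landmark pairs.

Two transform modes are provided.  ``consistent`` (default) rotates points
by the inter-image angle difference about the chest right-6th-rib landmark
with the standard planar rotation, then applies the per-axis scales and the
translations derived from the landmark spans — this chain recovers an exact
similarity transform exactly.  ``paper_literal`` reproduces an alternative
printed arithmetic in which the "rotation" step multiplies coordinates by
cos(theta1)cos(theta2) and sin(theta1)sin(theta2); it is kept for archaeology
and does not reduce to the identity even when both images share one angle.

Pixel coordinates are (x=column, y=row), origin top-left, y downward.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage import measure
from skimage.transform import hough_circle, hough_circle_peaks

from .errors import RegistrationError
from .layout import SensorLayout

__all__ = [
    "ColorSpec",
    "LandmarkSet",
    "SimilarityTransform",
    "GREEN_DISC",
    "RED_DISC",
    "extract_markers",
    "label_landmarks",
    "estimate_transform",
    "transform_points",
    "invert_points",
    "assign_channel_ids",
    "locate_channels",
]

LANDMARK_NAMES = ("sternoclavicular joint", "right 10th rib",
                  "right 6th rib", "left 6th rib")


@dataclass
class ColorSpec:
    """HSV window plus Hough radius range for one marker colour.

    ``hue_range`` is in degrees and may wrap through 0 (e.g. (345, 15) for
    red); ``sat_min``/``val_min`` reject the near-white background.
    """

    hue_range: tuple[float, float]
    sat_min: float = 0.4
    val_min: float = 0.25
    radius_range: tuple[int, int] = (4, 30)

    def mask(self, rgb: np.ndarray) -> np.ndarray:
        hsv = skcolor.rgb2hsv(rgb[..., :3])
        hue = hsv[..., 0] * 360.0
        lo, hi = self.hue_range
        if lo <= hi:
            in_hue = (hue >= lo) & (hue <= hi)
        else:  # window wraps through 0 degrees
            in_hue = (hue >= lo) | (hue <= hi)
        return in_hue & (hsv[..., 1] >= self.sat_min) & (hsv[..., 2] >= self.val_min)


GREEN_DISC = ColorSpec(hue_range=(90.0, 170.0))
RED_DISC = ColorSpec(hue_range=(340.0, 20.0))


@dataclass
class LandmarkSet:
    """The four registration landmarks of one image.

    ``points`` rows are ordered: sternoclavicular joint, right 10th rib,
    right 6th rib, left 6th rib.  ``source`` records which image they came
    from ('chest' or 'skeleton').
    """

    points: np.ndarray
    source: str = "chest"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.points.shape != (4, 2):
            raise RegistrationError(
                f"{self.source}: a landmark set needs exactly 4 points, "
                f"got {self.points.shape[0]}")
        if np.allclose(self.points[2], self.points[3]):
            raise RegistrationError(
                f"{self.source}: left/right 6th-rib landmarks coincide")


@dataclass
class SimilarityTransform:
    """Rotate / scale / translate chain mapping chest to skeleton pixels.

    theta1/theta2 are the angles (radians, from horizontal) of the 6th-rib
    baseline in the chest and skeleton images; eta_x/eta_y the axis scales;
    phi_x/phi_y the translations in pixels.  ``center`` is the rotation
    anchor (chest right-6th-rib landmark) used by the consistent mode.
    """

    theta1: float
    theta2: float
    eta_x: float
    eta_y: float
    phi_x: float
    phi_y: float
    center: tuple[float, float] = (0.0, 0.0)
    mode: str = "consistent"

    def __post_init__(self) -> None:
        if self.mode not in ("consistent", "paper_literal"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "consistent" and not (self.eta_x > 0 and self.eta_y > 0):
            raise ValueError("scale factors must be positive")


def _rotate_about(points: np.ndarray, angle: float,
                  center: tuple[float, float]) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    ctr = np.asarray(center)
    return (points - ctr) @ rot.T + ctr


def _literal_rotation(points: np.ndarray, theta1: float,
                      theta2: float) -> np.ndarray:
    out = np.empty_like(points)
    out[:, 0] = points[:, 0] * np.cos(theta1) * np.cos(theta2)
    out[:, 1] = points[:, 1] * np.sin(theta1) * np.sin(theta2)
    return out


def extract_markers(image: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Detect disc-marker centres of one colour; (n, 2) array of (x, y).

    The image is thresholded in HSV to a binary mask; each connected
    component is validated as a circle by the Circle Hough transform over
    ``spec.radius_range`` and its centre refined to sub-pixel precision by
    the component centroid.  Returns an empty array when nothing matches.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("an RGB image is required")
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 1) if img.max() <= 1 else img / 255.0
        img = (np.asarray(img) * 255).astype(np.uint8)
    mask = spec.mask(img / 255.0)
    labels = measure.label(mask)
    rmin, rmax = spec.radius_range
    min_area = 0.5 * np.pi * rmin ** 2
    centers = []
    radii = np.arange(max(2, rmin), rmax + 1)
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        # Hough vote on the component's edge pixels, padded local patch.
        pad = rmax + 2
        y0, x0, y1, x1 = region.bbox
        patch = (labels[max(0, y0 - pad): y1 + pad,
                        max(0, x0 - pad): x1 + pad] == region.label)
        edges = patch ^ _erode(patch)
        accum = hough_circle(edges, radii)
        acc, cx, cy, rad = hough_circle_peaks(accum, radii, total_num_peaks=1)
        if acc.size == 0 or acc[0] < 0.3:
            continue
        cy_img, cx_img = region.centroid  # sub-pixel refinement
        centers.append((cx_img, cy_img))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _erode(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[1:, :] &= mask[:-1, :]
    out[:-1, :] &= mask[1:, :]
    out[:, 1:] &= mask[:, :-1]
    out[:, :-1] &= mask[:, 1:]
    return out


def label_landmarks(centers: np.ndarray, source: str = "chest") -> LandmarkSet:
    """Assign the four detected landmark centres to their anatomical roles.

    In a frontal image the sternoclavicular joint is topmost, the right 10th
    rib bottommost, and of the 6th-rib pair the anatomical right appears at
    smaller image x.
    """
    pts = np.asarray(centers, dtype=float).reshape(-1, 2)
    if pts.shape[0] != 4:
        raise RegistrationError(
            f"{source}: expected 4 landmark markers, found {pts.shape[0]}")
    by_y = pts[np.argsort(pts[:, 1])]
    top, bottom = by_y[0], by_y[-1]
    middle = by_y[1:3][np.argsort(by_y[1:3, 0])]
    ordered = np.vstack([top, bottom, middle[0], middle[1]])
    return LandmarkSet(points=ordered, source=source)


def estimate_transform(chest: LandmarkSet, skeleton: LandmarkSet,
                       mode: str = "consistent") -> SimilarityTransform:
    """Estimate the chest-to-skeleton transform from the landmark pairs.

    The baseline angle in each image comes from the right-to-left 6th-rib
    chord; the x scale from the 6th-rib span, the y scale from the joint to
    10th-rib span; the translation anchors the right 6th rib in x and the
    sternoclavicular joint in y.
    """
    (p1, p2, p3, p4) = chest.points
    (v1, v2, v3, v4) = skeleton.points
    if np.allclose(p3, p4):
        raise RegistrationError("chest 6th-rib baseline has zero length")
    theta1 = float(np.arctan2(p4[1] - p3[1], p4[0] - p3[0]))
    theta2 = float(np.arctan2(v4[1] - v3[1], v4[0] - v3[0]))

    if mode == "consistent":
        rotated = _rotate_about(chest.points, theta2 - theta1, tuple(p3))
    elif mode == "paper_literal":
        rotated = _literal_rotation(chest.points, theta1, theta2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r1, r2, r3, r4 = rotated
    dx = r4[0] - r3[0]
    dy = r2[1] - r1[1]
    if dx == 0 or dy == 0:
        raise RegistrationError("rotated landmarks give a zero span")
    eta_x = (v4[0] - v3[0]) / dx
    eta_y = (v2[1] - v1[1]) / dy
    if mode == "consistent" and (eta_x <= 0 or eta_y <= 0):
        raise RegistrationError(
            f"non-positive scale (eta_x={eta_x:.3g}, eta_y={eta_y:.3g}); "
            "check landmark ordering")
    phi_x = v3[0] - eta_x * r3[0]
    phi_y = v1[1] - eta_y * r1[1]
    return SimilarityTransform(theta1=theta1, theta2=theta2, eta_x=eta_x,
                               eta_y=eta_y, phi_x=phi_x, phi_y=phi_y,
                               center=(float(p3[0]), float(p3[1])), mode=mode)


def transform_points(points: np.ndarray, T: SimilarityTransform) -> np.ndarray:
    """Map chest-image points into skeleton-image coordinates."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if T.mode == "consistent":
        rotated = _rotate_about(pts, T.theta2 - T.theta1, T.center)
    else:
        rotated = _literal_rotation(pts, T.theta1, T.theta2)
    out = np.empty_like(rotated)
    out[:, 0] = T.eta_x * rotated[:, 0] + T.phi_x
    out[:, 1] = T.eta_y * rotated[:, 1] + T.phi_y
    return out


def invert_points(points: np.ndarray, T: SimilarityTransform) -> np.ndarray:
    """Analytic inverse of :func:`transform_points` (consistent mode only)."""
    if T.mode != "consistent":
        raise ValueError("the literal chain is not invertible in general")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    unscaled = np.empty_like(pts)
    unscaled[:, 0] = (pts[:, 0] - T.phi_x) / T.eta_x
    unscaled[:, 1] = (pts[:, 1] - T.phi_y) / T.eta_y
    return _rotate_about(unscaled, T.theta1 - T.theta2, T.center)


def assign_channel_ids(centers: np.ndarray) -> np.ndarray:
    """Row-major ordering of detected sensor centres.

    Centres are clustered into rows with a tolerance of half the median
    nearest-neighbour distance, rows sorted by y, and each row by x; the
    returned permutation lists the centre indices in channel order 1..n.
    """
    pts = np.asarray(centers, dtype=float).reshape(-1, 2)
    n = pts.shape[0]
    if n <= 1:
        return np.arange(n)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    tol = 0.5 * float(np.median(d.min(axis=1)))
    order_y = np.argsort(pts[:, 1], kind="stable")
    rows: list[list[int]] = [[int(order_y[0])]]
    row_y = pts[order_y[0], 1]
    for idx in order_y[1:]:
        if pts[idx, 1] - row_y > tol:
            rows.append([])
            row_y = pts[idx, 1]
        rows[-1].append(int(idx))
    out = []
    for row in rows:
        out.extend(sorted(row, key=lambda i: pts[i, 0]))
    return np.asarray(out, dtype=int)


def locate_channels(chest_photo: np.ndarray, skeleton_image: np.ndarray,
                    sensor_spec: ColorSpec = GREEN_DISC,
                    landmark_spec: ColorSpec = RED_DISC,
                    mode: str = "consistent",
                    skeleton_landmark_spec: ColorSpec | None = None
                    ) -> SensorLayout:
    """End-to-end channel localisation: detect, register, transform.

    Extracts sensor and landmark markers from the chest photo and landmark
    markers from the skeleton image, estimates the transform and returns the
    sensor layout in skeleton-image pixel coordinates with channel ids
    assigned row-major.
    """
    chest_lm = extract_markers(chest_photo, landmark_spec)
    if chest_lm.shape[0] != 4:
        raise RegistrationError(
            f"chest photo: expected 4 landmark discs "
            f"(hue {landmark_spec.hue_range}), found {chest_lm.shape[0]}")
    skel_spec = skeleton_landmark_spec or landmark_spec
    skel_lm = extract_markers(skeleton_image, skel_spec)
    if skel_lm.shape[0] != 4:
        raise RegistrationError(
            f"skeleton image: expected 4 landmark discs "
            f"(hue {skel_spec.hue_range}), found {skel_lm.shape[0]}")
    sensors = extract_markers(chest_photo, sensor_spec)
    if sensors.shape[0] == 0:
        raise RegistrationError("chest photo: no sensor markers detected")
    chest = label_landmarks(chest_lm, source="chest")
    skeleton = label_landmarks(skel_lm, source="skeleton")
    T = estimate_transform(chest, skeleton, mode=mode)
    order = assign_channel_ids(sensors)
    mapped = transform_points(sensors[order], T)
    return SensorLayout(coords=mapped)
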