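"""Geometric fluorescence scanning: image stacks -> distance profiles.

Three scan geometries are supported, mirroring the acquisition layouts of
wound, droplet/trichome and vein experiments:

* ``radial_point`` — equiangular radii departing from a single anchor point
  (default 100 lines);
* ``arc_circle`` — radii starting on the circle through three edge points,
  sweeping the arc between the first two points that does not contain the
  third, pointing radially outward;
* ``vein_transects`` — equidistant lines perpendicular to a vein segment
  (default 10 lines of 500 um).

Lines are sampled every pixel with bilinear interpolation; samples leaving
the image are excluded from the cross-line mean (not zero-filled).
Coordinates are 0-based pixel centres, x right, y down.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import DataError, GeometryError
from .stack import ImageStack

__all__ = [
    "ScanGeometry",
    "ProfileSet",
    "circle_from_three_points",
    "build_lines",
    "scan_stack",
]

DEFAULT_N_LINES = {"radial_point": 100, "arc_circle": 100, "vein_transects": 10}


@dataclass
class ScanGeometry:
    """Scan layout: mode, anchor points (px) and line count/length."""

    mode: str
    points: list[tuple[float, float]]  # anchor / 3 edge points / segment ends
    n_lines: int | None = None
    line_length: float = 700.0  # um
    transect_side: int = 1  # +1/-1: which normal of the vein segment

    def __post_init__(self) -> None:
        if self.mode not in DEFAULT_N_LINES:
            raise GeometryError(f"unknown scan mode {self.mode!r}")
        if self.n_lines is None:
            self.n_lines = DEFAULT_N_LINES[self.mode]
        if self.n_lines < 1:
            raise GeometryError("n_lines must be >= 1")
        if self.line_length <= 0:
            raise GeometryError("line_length must be positive")
        need = {"radial_point": 1, "arc_circle": 3, "vein_transects": 2}[self.mode]
        if len(self.points) != need:
            raise GeometryError(f"mode {self.mode!r} needs {need} point(s), "
                                f"got {len(self.points)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScanGeometry":
        d = json.loads(Path(path).read_text())
        return cls(mode=d["mode"], points=[tuple(p) for p in d["points"]],
                   n_lines=d.get("n_lines"),
                   line_length=d.get("line_length_um", 700.0),
                   transect_side=d.get("transect_side", 1))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mode": self.mode, "points": [list(p) for p in self.points],
            "n_lines": self.n_lines, "line_length_um": self.line_length,
            "transect_side": self.transect_side}, indent=1))


@dataclass
class ProfileSet:
    """Cross-line mean intensity per (distance from anchor, frame time)."""

    distances: np.ndarray  # um, strictly increasing from 0 at the anchor
    times: np.ndarray  # s
    intensity: np.ndarray  # (n_distances, n_times)
    n_lines_used: np.ndarray = field(default=None)  # lines contributing per distance
    pixel_size: float = 1.0  # um/px, the distance grid step

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.distances.size, self.times.size):
            raise DataError("intensity must be (n_distances, n_times)")
        if np.any(np.diff(self.distances) <= 0):
            raise DataError("distances must be strictly increasing")
        if self.n_lines_used is None:
            self.n_lines_used = np.full(self.distances.size, 1)

    def to_csv(self, path: str | Path) -> None:
        """Matrix CSV: rows = distances (um), columns = frame times (s)."""
        df = pd.DataFrame(self.intensity, index=self.distances,
                          columns=self.times)
        df.index.name = "distance_um"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, pixel_size: float = 1.0) -> "ProfileSet":
        df = pd.read_csv(path, index_col=0)
        return cls(distances=df.index.to_numpy(float),
                   times=np.array([float(c) for c in df.columns]),
                   intensity=df.to_numpy(float), pixel_size=pixel_size)


def circle_from_three_points(p1, p2, p3):
    """Centre and radius (px) of the circle through three points.

    Raises :class:`GeometryError` for coincident or collinear points.
    """
    pts = np.asarray([p1, p2, p3], dtype=float)
    if len({tuple(p) for p in pts}) < 3:
        raise GeometryError("points must be pairwise distinct")
    # perpendicular-bisector linear system
    a = 2 * (pts[1:] - pts[0])
    b = (pts[1:] ** 2 - pts[0] ** 2).sum(axis=1)
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    if abs(det) < 1e-9 * max(np.abs(a).max(), 1.0) ** 2:
        raise GeometryError("points are collinear")
    center = np.linalg.solve(a, b)
    radius = float(np.linalg.norm(pts[0] - center))
    return (float(center[0]), float(center[1])), radius


def _arc_angles(p1, p2, p3, center, n: int) -> np.ndarray:
    """Equally spaced angles from p1 to p2 along the arc not containing p3."""
    ang = [np.arctan2(p[1] - center[1], p[0] - center[0]) for p in (p1, p2, p3)]
    a1, a2, a3 = ang
    # sweep counter-clockwise from a1 to a2; flip if that arc contains a3
    ccw = (a2 - a1) % (2 * np.pi)
    if ccw == 0:
        raise GeometryError("degenerate arc: endpoints coincide on the circle")
    pos3 = (a3 - a1) % (2 * np.pi)
    if pos3 < ccw:  # a3 inside the ccw arc -> use the other one
        span = ccw - 2 * np.pi
    else:
        span = ccw
    if n == 1:
        return np.array([a1 + span / 2])
    return a1 + span * np.arange(n) / (n - 1)


def build_lines(geometry: ScanGeometry, pixel_size: float,
                image_shape: tuple[int, int] | None = None):
    """Construct the sampling lines for a geometry.

    Returns ``(starts, dirs, n_samples)``: per line the start point (px), the
    unit direction, and the per-pixel sample count after clipping to the
    image (``n_samples`` is uniform when no clipping occurs).
    """
    if pixel_size <= 0:
        raise GeometryError("pixel_size must be positive")
    n = geometry.n_lines
    pts = [np.asarray(p, dtype=float) for p in geometry.points]
    if geometry.mode == "radial_point":
        angles = 2 * np.pi * np.arange(n) / n
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        starts = np.tile(pts[0], (n, 1))
    elif geometry.mode == "arc_circle":
        center, radius = circle_from_three_points(*geometry.points)
        c = np.asarray(center)
        angles = _arc_angles(pts[0], pts[1], pts[2], c, n)
        dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        starts = c + radius * dirs  # radii start on the circle, point outward
    else:  # vein_transects
        a, b = pts
        seg = b - a
        seg_len = np.linalg.norm(seg)
        if seg_len == 0:
            raise GeometryError("vein segment endpoints coincide")
        tangent = seg / seg_len
        normal = geometry.transect_side * np.array([tangent[1], -tangent[0]])
        if n == 1:
            frac = np.array([0.5])
        else:
            frac = np.arange(n) / (n - 1)
        starts = a + frac[:, None] * seg
        dirs = np.tile(normal, (n, 1))

    n_total = int(np.floor(geometry.line_length / pixel_size)) + 1
    if image_shape is None:
        n_samples = np.full(n, n_total)
    else:
        h, w = image_shape
        n_samples = np.empty(n, dtype=int)
        steps = np.arange(n_total)
        for i in range(n):
            xy = starts[i] + steps[:, None] * dirs[i]
            inside = ((xy[:, 0] >= 0) & (xy[:, 0] <= w - 1)
                      & (xy[:, 1] >= 0) & (xy[:, 1] <= h - 1))
            bad = np.nonzero(~inside)[0]
            n_samples[i] = bad[0] if bad.size else n_total
    return starts, dirs, n_samples


def scan_stack(stack: ImageStack, geometry: ScanGeometry) -> ProfileSet:
    """Average bilinearly interpolated intensity over lines, per distance/frame."""
    starts, dirs, n_samples = build_lines(geometry, stack.pixel_size,
                                          stack.shape)
    n_total = int(n_samples.max())
    if n_total == 0:
        raise GeometryError("all scan lines fall outside the image")
    steps = np.arange(n_total)
    # (n_lines, n_samples, 2) sample coordinates
    xy = starts[:, None, :] + steps[None, :, None] * dirs[:, None, :]
    valid = steps[None, :] < n_samples[:, None]
    coords = np.stack([xy[..., 1].ravel(), xy[..., 0].ravel()])  # (row, col)

    n_lines = starts.shape[0]
    profiles = np.empty((n_total, stack.n_frames))
    counts = valid.sum(axis=0).astype(float)
    for k in range(stack.n_frames):
        vals = map_coordinates(stack.frames[k], coords, order=1,
                               mode="constant", cval=np.nan)
        vals = vals.reshape(n_lines, n_total)
        vals[~valid] = 0.0
        with np.errstate(invalid="ignore"):
            profiles[:, k] = vals.sum(axis=0) / counts
    keep = counts > 0
    distances = steps * stack.pixel_size
    return ProfileSet(distances=distances[keep], times=stack.times,
                      intensity=profiles[keep], n_lines_used=counts[keep],
                      pixel_size=stack.pixel_size)
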