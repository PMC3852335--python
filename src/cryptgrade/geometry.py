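"""Planar polygon primitives shared across segmentation and feature modules.

Coordinates are 0-based pixel indices, x rightward, y downward.  Closed
boundaries are stored as open rings (last vertex != first) oriented
counter-clockwise in this left-handed pixel frame.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import shapely


@dataclass(frozen=True)
class Boundary:
    """An ordered sequence of 2-D points in pixel coordinates.

    ``closed=True`` denotes a polygon ring (crypt outline); ``closed=False``
    an open polyline (muscularis edge).
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if self.closed and len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if self.closed and len(v) < 3:
            raise ValueError("closed boundary needs >= 3 vertices")
        if len(v) < 2:
            raise ValueError("boundary needs >= 2 vertices")
        d = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(d == 0.0):
            keep = np.concatenate([[True], d > 0.0])
            v = v[keep]
            if (self.closed and len(v) < 3) or len(v) < 2:
                raise ValueError("boundary degenerates to repeated vertices")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def x(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.vertices[:, 1]

    def translated(self, dx: float, dy: float) -> "Boundary":
        return Boundary(self.vertices + np.array([dx, dy]), closed=self.closed)


@dataclass
class ContourSet:
    """Segmentation result for one image: crypt rings plus muscularis edge."""

    crypts: List[Boundary] = field(default_factory=list)
    muscularis: Optional[Boundary] = None


def polygon_area(vertices: np.ndarray) -> float:
    """Signed shoelace area (positive = counter-clockwise in a y-up frame)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Continuous (shoelace) centroid of a simple polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0.0:
        raise ValueError("degenerate polygon (zero area)")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Orient a ring counter-clockwise (pixel frame: negative shoelace sign)."""
    # In the y-down pixel frame a visually counter-clockwise ring has
    # negative shoelace area; flip when positive.
    if polygon_area(vertices) > 0:
        return np.asarray(vertices, dtype=float)[::-1].copy()
    return np.asarray(vertices, dtype=float)


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper or touching intersection of segments p1p2 and p3p4."""
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return True
    return False


def is_simple_polygon(vertices: np.ndarray) -> bool:
    """True when no two non-adjacent edges of the ring cross."""
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


def resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a ring to ``n`` vertices equally spaced along its perimeter."""
    v = np.asarray(vertices, dtype=float)
    ring = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("zero-perimeter boundary")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, ring[:, 0])
    y = np.interp(t, s, ring[:, 1])
    return np.column_stack([x, y])


def point_in_polygon(point: Sequence[float], vertices: np.ndarray) -> bool:
    """Containment test including the boundary itself."""
    poly = shapely.Polygon(np.asarray(vertices, dtype=float))
    return bool(shapely.intersects_xy(poly, float(point[0]), float(point[1])))


def perimeter(vertices: np.ndarray, closed: bool = True) -> float:
    v = np.asarray(vertices, dtype=float)
    if closed:
        v = np.vstack([v, v[:1]])
    return float(np.sum(np.linalg.norm(np.diff(v, axis=0), axis=1)))
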