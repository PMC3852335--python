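"""Crypt density via image moments and the Euclidean minimum spanning tree.

Centroids come from the discrete moments of the filled crypt mask,

    M_pq = sum_x sum_y x^p y^q f(x, y),  f in {0, 1},
    xbar = M10 / M00,  ybar = M01 / M00,

the MST over all centroids is built with Kruskal's algorithm on the complete
Euclidean graph, and the density feature is the mean MST edge length
normalized by the maximum distance encountered in the tree.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import shapely

from .geometry import Boundary


@dataclass(frozen=True)
class CryptCentroid:
    """First-order moment centroid of one filled crypt region."""

    x: float
    y: float
    m00: float

    def __post_init__(self) -> None:
        if self.m00 <= 0:
            raise ValueError("M00 must be positive")

    @property
    def point(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class MSTResult:
    """Edges (i, j, weight) and total weight of the minimum spanning tree."""

    edges: Tuple[Tuple[int, int, float], ...]
    total_weight: float

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.edges], dtype=float)


def rasterize_boundary(boundary: Boundary) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel-centre coordinates (x, y) covered by the filled polygon,
    boundary pixels included."""
    v = boundary.vertices
    x0, y0 = np.floor(v.min(axis=0)).astype(int)
    x1, y1 = np.ceil(v.max(axis=0)).astype(int)
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    poly = shapely.Polygon(v)
    if not poly.is_valid:
        poly = poly.buffer(0)
    inside = shapely.intersects_xy(poly, gx.ravel().astype(float), gy.ravel().astype(float))
    return gx.ravel()[inside], gy.ravel()[inside]


def centroid_from_boundary(boundary: Boundary) -> CryptCentroid:
    """Moment centroid of the filled polygon's binary mask."""
    if not boundary.closed:
        raise ValueError("centroid requires a closed boundary")
    px, py = rasterize_boundary(boundary)
    m00 = float(len(px))
    if m00 == 0:
        raise ValueError("zero-area boundary")
    return CryptCentroid(float(px.sum()) / m00, float(py.sum()) / m00, m00)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def kruskal_mst(points: Sequence[Sequence[float]]) -> MSTResult:
    """Minimum spanning tree of the complete Euclidean graph.

    Edges are processed in stable (weight, i, j) order with i < j, making
    the returned tree deterministic under ties; duplicate points yield
    zero-weight edges.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        raise ValueError("need at least one point")
    if n == 1:
        return MSTResult((), 0.0)
    cand = []
    for i in range(n):
        d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
        for k, j in enumerate(range(i + 1, n)):
            cand.append((float(d[k]), i, j))
    cand.sort()
    uf = _UnionFind(n)
    edges: List[Tuple[int, int, float]] = []
    for w, i, j in cand:
        if uf.union(i, j):
            edges.append((i, j, w))
            if len(edges) == n - 1:
                break
    return MSTResult(tuple(edges), float(sum(w for _, _, w in edges)))


@dataclass(frozen=True)
class SpacingFeature:
    value: float
    sparse: bool = False
    mean_edge: float = float("nan")
    max_edge: float = float("nan")


def crypt_spacing_feature(
    centroids: Sequence[CryptCentroid] | np.ndarray,
    mode: str = "mst_edge",
) -> SpacingFeature:
    """Normalized average inter-crypt spacing in (0, 1].

    mean MST edge weight / maximum distance encountered, where the
    denominator is the maximum MST edge (default) or the maximum pairwise
    distance (``mode='pairwise'``).  With zero or one crypt the feature
    saturates at 1.0 (maximal sparsity) with the ``sparse`` flag set.
    """
    if mode not in ("mst_edge", "pairwise"):
        raise ValueError("mode must be 'mst_edge' or 'pairwise'")
    pts = np.array([c.point if isinstance(c, CryptCentroid) else np.asarray(c, dtype=float)
                    for c in centroids]).reshape(-1, 2)
    if len(pts) <= 1:
        return SpacingFeature(1.0, sparse=True)
    mst = kruskal_mst(pts)
    w = mst.weights
    mean_edge, max_edge = float(w.mean()), float(w.max())
    if mode == "pairwise":
        diffs = pts[:, None, :] - pts[None, :, :]
        denom = float(np.linalg.norm(diffs, axis=2).max())
    else:
        denom = max_edge
    value = 1.0 if denom == 0.0 else float(w.mean() / denom)
    return SpacingFeature(value, sparse=False, mean_edge=mean_edge, max_edge=max_edge)
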