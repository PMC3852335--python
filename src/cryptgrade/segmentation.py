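"""Preprocessing and active-contour (snake) localization of crypts and
muscularis mucosa.

The pipeline is: background subtraction (a paired background image, or a
morphological estimate when none is supplied), contrast rescaling, median
filtering; Otsu thresholding to seed one initial contour per candidate dark
component; greedy snake evolution of each contour toward the gradient ridge
of the lumen edge; and extraction of the muscularis upper edge as the
largest dark component touching the bottom border.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import shapely
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .geometry import Boundary, ContourSet, ensure_ccw, polygon_area, polygon_centroid, resample_closed
from .synthetic import LabeledImage


@dataclass(frozen=True)
class SnakeConfig:
    """Energy weights and termination settings of the greedy snake.

    The snake minimizes
    ``E = alpha*E_continuity + beta*E_curvature + gamma*E_image + kappa*E_constraint``
    where the image term is the negative gradient magnitude of the smoothed
    image and the constraint term is an inward pressure that prevents
    expansion beyond twice the initial mean radius.
    """

    alpha: float = 0.4
    beta: float = 0.2
    gamma: float = 1.0
    kappa: float = 0.1
    max_iters: int = 500
    move_tol: float = 0.5
    n_vertices: int = 64
    window: int = 7          # odd search-window side, per-vertex local moves
    smooth_sigma: float = 2.0
    dark_crypts: bool = True  # crypt lumina darker than stroma

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma, self.kappa) < 0:
            raise ValueError("energy weights must be non-negative")
        if self.n_vertices < 8:
            raise ValueError("n_vertices must be >= 8")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")


@dataclass
class SnakeResult:
    boundary: Boundary
    converged: bool
    iterations: int
    energies: List[float]
    failed: bool = False


def _to_gray(image: LabeledImage) -> np.ndarray:
    return np.asarray(image.pixels, dtype=float)


def estimate_background(gray: np.ndarray, radius: int = 60, dark_objects: bool = True,
                        downsample: int = 4) -> np.ndarray:
    """Morphological background estimate with structuring radius much larger
    than a crypt radius.

    Grey closing fills objects darker than their surround (the default crypt
    polarity), leaving the smooth illumination-modulated stroma; opening is
    used for inverted polarity.  Computed on a downsampled copy since the
    background is smooth by construction.
    """
    small = gray[::downsample, ::downsample]
    size = 2 * max(1, radius // downsample) + 1
    op = ndimage.grey_closing if dark_objects else ndimage.grey_opening
    bg_small = op(small, size=(size, size), mode="nearest")
    bg = resize(bg_small, gray.shape, order=1, mode="edge", anti_aliasing=False)
    return bg


def preprocess(
    image: LabeledImage,
    background: Optional[LabeledImage] = None,
    median_radius: int = 2,
    background_radius: int = 60,
    dark_crypts: bool = True,
) -> LabeledImage:
    """Background-subtract, rescale to the full 0-255 range, median-filter."""
    gray = _to_gray(image)
    if background is not None:
        bg = _to_gray(background)
        if bg.shape != gray.shape:
            raise ValueError("background dimensions must match the image")
    else:
        bg = estimate_background(gray, radius=background_radius, dark_objects=dark_crypts)
    diff = gray - bg
    lo, hi = float(diff.min()), float(diff.max())
    if hi - lo < 1e-9:
        out = np.zeros_like(diff)
    else:
        out = (diff - lo) * (255.0 / (hi - lo))
    size = 2 * int(median_radius) + 1
    out = ndimage.median_filter(out, size=size, mode="nearest")
    return LabeledImage(out, grade=image.grade, source_id=image.source_id)


def _dark_mask(gray: np.ndarray, dark_crypts: bool = True) -> np.ndarray:
    if float(np.ptp(gray)) < 1e-9:
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    return gray < t if dark_crypts else gray > t


def initialize_contours(
    clean: LabeledImage,
    min_area: Optional[float] = None,
    max_area: Optional[float] = None,
    n_vertices: int = 64,
    dilate: float = 3.0,
    dark_crypts: bool = True,
) -> List[Boundary]:
    """One initial contour per thresholded, hole-filled, size-filtered
    component: the component's convex hull dilated outward and resampled to
    ``n_vertices``."""
    gray = _to_gray(clean)
    h, w = gray.shape
    if min_area is None:
        min_area = 3e-4 * h * w
    if max_area is None:
        max_area = 0.04 * h * w
    if min_area >= max_area:
        raise ValueError("min_area must be smaller than max_area")
    mask = _dark_mask(gray, dark_crypts)
    if not mask.any():
        return []
    mask = ndimage.binary_fill_holes(mask)
    labels, _ = ndimage.label(mask)
    out: List[Boundary] = []
    for region in measure.regionprops(labels):
        if not (min_area <= region.area <= max_area):
            continue
        coords = region.coords  # (row, col)
        pts = shapely.MultiPoint(np.column_stack([coords[:, 1], coords[:, 0]]).astype(float))
        hull = pts.convex_hull.buffer(dilate, quad_segs=4)
        if hull.geom_type != "Polygon" or hull.area < 3.0:
            continue
        ring = np.asarray(hull.exterior.coords)[:-1]
        verts = resample_closed(ring, n_vertices)
        out.append(Boundary(ensure_ccw(verts), closed=True))
    # deterministic order: by centroid (y, x)
    out.sort(key=lambda b: (round(float(np.mean(b.y)), 3), round(float(np.mean(b.x)), 3)))
    return out


def gradient_magnitude(clean: LabeledImage, sigma: float = 2.0) -> np.ndarray:
    return ndimage.gaussian_gradient_magnitude(_to_gray(clean), sigma=sigma)


def _total_energy(v: np.ndarray, grad: np.ndarray, cfg: SnakeConfig,
                  center0: np.ndarray, rcap: float) -> float:
    d1 = v - np.roll(v, 1, axis=0)
    cont = np.sum(d1 ** 2)
    d2 = np.roll(v, 1, axis=0) - 2 * v + np.roll(v, -1, axis=0)
    curv = np.sum(d2 ** 2)
    xi = np.clip(v[:, 0].astype(int), 0, grad.shape[1] - 1)
    yi = np.clip(v[:, 1].astype(int), 0, grad.shape[0] - 1)
    img = -float(np.sum(grad[yi, xi]))
    r = np.linalg.norm(v - center0, axis=1)
    con = float(np.sum(np.maximum(0.0, r - rcap) ** 2))
    return cfg.alpha * cont + cfg.beta * curv + cfg.gamma * img + cfg.kappa * con


def evolve_snake(
    initial: Boundary,
    clean: LabeledImage,
    config: SnakeConfig = SnakeConfig(),
    grad: Optional[np.ndarray] = None,
) -> SnakeResult:
    """Greedy per-vertex minimization of the snake energy.

    Each vertex in turn moves to the lowest-energy position in an odd
    ``window x window`` integer neighbourhood; a move is accepted only when
    it strictly lowers the terms it touches, so the total energy is
    non-increasing across accepted moves.  Terminates when the largest
    per-vertex displacement of a sweep falls below ``move_tol`` or after
    ``max_iters`` sweeps.
    """
    if not initial.closed:
        raise ValueError("snake requires a closed initial contour")
    if grad is None:
        grad = gradient_magnitude(clean, sigma=config.smooth_sigma)
    h, w = grad.shape
    v = np.rint(initial.vertices).astype(float)
    v[:, 0] = np.clip(v[:, 0], 0, w - 1)
    v[:, 1] = np.clip(v[:, 1], 0, h - 1)
    n = len(v)
    center0 = polygon_centroid(initial.vertices)
    rcap = 2.0 * float(np.mean(np.linalg.norm(initial.vertices - center0, axis=1)))

    half = config.window // 2
    oy, ox = np.mgrid[-half:half + 1, -half:half + 1]
    offsets = np.column_stack([ox.ravel(), oy.ravel()]).astype(float)  # (m, 2)

    a, b_, g, k = config.alpha, config.beta, config.gamma, config.kappa
    energies = [_total_energy(v, grad, config, center0, rcap)]
    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        max_move = 0.0
        for i in range(n):
            vm1, vp1 = v[i - 1], v[(i + 1) % n]
            vm2, vp2 = v[i - 2], v[(i + 2) % n]
            cand = v[i] + offsets
            cand[:, 0] = np.clip(cand[:, 0], 0, w - 1)
            cand[:, 1] = np.clip(cand[:, 1], 0, h - 1)
            # local terms touched by vertex i
            cont = np.sum((cand - vm1) ** 2, axis=1) + np.sum((vp1 - cand) ** 2, axis=1)
            curv = (np.sum((vm2 - 2 * vm1 + cand) ** 2, axis=1)
                    + np.sum((vm1 - 2 * cand + vp1) ** 2, axis=1)
                    + np.sum((cand - 2 * vp1 + vp2) ** 2, axis=1))
            xi = cand[:, 0].astype(int)
            yi = cand[:, 1].astype(int)
            img = -grad[yi, xi]
            r = np.linalg.norm(cand - center0, axis=1)
            con = np.maximum(0.0, r - rcap) ** 2
            e = a * cont + b_ * curv + g * img + k * con
            cur = float(e[len(e) // 2])  # zero offset is the window centre
            j = int(np.argmin(e))
            if e[j] < cur - 1e-9:
                move = float(np.linalg.norm(cand[j] - v[i]))
                v[i] = cand[j]
                max_move = max(max_move, move)
        energies.append(_total_energy(v, grad, config, center0, rcap))
        if max_move < config.move_tol:
            converged = True
            break

    if abs(polygon_area(v)) < 3.0:
        return SnakeResult(initial, False, it, energies, failed=True)
    # drop consecutive duplicates the integer moves may have created
    keep = np.ones(len(v), dtype=bool)
    for i in range(1, len(v)):
        if np.all(v[i] == v[i - 1]):
            keep[i] = False
    v = v[keep]
    if len(v) < 3:
        return SnakeResult(initial, False, it, energies, failed=True)
    return SnakeResult(Boundary(v, closed=True), converged, it, energies)


def extract_muscularis(clean: LabeledImage, dark_crypts: bool = True,
                       column_stride: int = 2) -> Optional[Boundary]:
    """Upper edge of the largest dark component touching the bottom border,
    as an open polyline over the columns it covers."""
    gray = _to_gray(clean)
    mask = _dark_mask(gray, dark_crypts)
    if not mask.any():
        return None
    labels, nlab = ndimage.label(mask)
    bottom = labels[-1, :]
    cand = np.unique(bottom[bottom > 0])
    if cand.size == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=cand)
    lab = int(cand[int(np.argmax(sizes))])
    comp = labels == lab
    cols = np.where(comp.any(axis=0))[0]
    if cols.size < 2:
        return None
    pts = []
    for c in cols[::column_stride]:
        rows = np.where(comp[:, c])[0]
        pts.append((float(c), float(rows.min())))
    if len(pts) < 2:
        return None
    return Boundary(np.array(pts), closed=False)


def segment_biopsy(
    image: LabeledImage,
    background: Optional[LabeledImage] = None,
    config: SnakeConfig = SnakeConfig(),
    min_area: Optional[float] = None,
    max_area: Optional[float] = None,
    min_solidity: float = 0.5,
    median_radius: int = 2,
    background_radius: int = 60,
) -> ContourSet:
    """Full segmentation: preprocess, seed contours, evolve snakes, filter,
    and extract the muscularis edge."""
    clean = preprocess(image, background, median_radius=median_radius,
                       background_radius=background_radius, dark_crypts=config.dark_crypts)
    h, w = clean.pixels.shape
    if min_area is None:
        min_area = 3e-4 * h * w
    if max_area is None:
        max_area = 0.04 * h * w
    initial = initialize_contours(clean, min_area=min_area, max_area=max_area,
                                  n_vertices=config.n_vertices, dark_crypts=config.dark_crypts)
    grad = gradient_magnitude(clean, sigma=config.smooth_sigma)
    crypts: List[Boundary] = []
    for init in initial:
        res = evolve_snake(init, clean, config, grad=grad)
        if res.failed:
            continue
        b = res.boundary
        area = abs(polygon_area(b.vertices))
        if not (min_area * 0.3 <= area <= max_area):
            continue
        poly = shapely.Polygon(b.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        hull_area = poly.convex_hull.area
        if hull_area <= 0 or poly.area / hull_area < min_solidity:
            continue
        crypts.append(b)
    # enforce pairwise non-nesting: drop any crypt whose centroid falls
    # inside another (keep the larger)
    keep = [True] * len(crypts)
    cents = [polygon_centroid(c.vertices) for c in crypts]
    areas = [abs(polygon_area(c.vertices)) for c in crypts]
    for i in range(len(crypts)):
        for j in range(len(crypts)):
            if i == j or not keep[i]:
                continue
            if areas[i] <= areas[j] and i != j:
                poly_j = shapely.Polygon(crypts[j].vertices)
                if not poly_j.is_valid:
                    poly_j = poly_j.buffer(0)
                if poly_j.contains(shapely.Point(cents[i])) and areas[i] < areas[j]:
                    keep[i] = False
    crypts = [c for c, k in zip(crypts, keep) if k]
    muscularis = extract_muscularis(clean, dark_crypts=config.dark_crypts)
    return ContourSet(crypts=crypts, muscularis=muscularis)
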