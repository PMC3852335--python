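"""Grade-parameterized synthetic mucosa images with exact ground truth.

The generator emulates a well-oriented 10x field of colonic mucosa: dark
star-shaped crypt lumina over lighter stroma, a dark muscularis band along
the bottom edge, additive Gaussian sensor noise and a smooth multiplicative
illumination field.  Every primitive (crypt outlines, centroids, muscularis
edge, grade) is recorded so downstream segmentation and feature stages can
be validated without clinical material.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from skimage.draw import polygon as draw_polygon
from scipy import ndimage

from .geometry import Boundary, polygon_centroid
from .grades import DEFAULT_GRADE_PARAMS, GRADES, Grade, GradeParams

# Gray levels of the scene primitives (8-bit scale).
STROMA_LEVEL = 185.0
LUMEN_LEVEL = 70.0
MUSCULARIS_LEVEL = 60.0
NOISE_SIGMA = 5.0
ILLUMINATION_AMPLITUDE = 0.10


@dataclass
class LabeledImage:
    """A pixel grid with optional grade label and provenance metadata."""

    pixels: np.ndarray
    grade: Optional[Grade] = None
    source_id: str = ""
    color: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


@dataclass
class GroundTruth:
    """Exact generated primitives of one synthetic field."""

    crypt_boundaries: List[Boundary]
    crypt_centroids: np.ndarray  # (n, 2), x/y pixel coordinates
    muscularis_polyline: Boundary
    grade: Grade

    def __post_init__(self) -> None:
        if len(self.crypt_boundaries) != len(self.crypt_centroids):
            raise ValueError("one centroid per boundary required")


def generate_crypt_boundary(
    base_radius: float,
    distortion: float,
    n_harmonics: int = 4,
    rng_seed: int | np.random.Generator = 0,
    n_vertices: int = 180,
    center: Tuple[float, float] = (0.0, 0.0),
) -> Boundary:
    """Star-shaped crypt outline with harmonic radius perturbation.

    The radius about the centre is
    ``r(theta) = base_radius * (1 + distortion * sum_h c_h cos(h*theta + phi_h))``
    with the harmonic coefficients rescaled so their summed amplitude is at
    most 0.8, which guarantees ``r > 0`` for any distortion in [0, 1].
    Harmonics start at order 2: a pure first harmonic mostly displaces the
    outline rather than distorting it.
    """
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    if not 0.0 <= distortion <= 1.0:
        raise ValueError("distortion must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed) if isinstance(rng_seed, (int, np.integer)) else rng_seed
    orders = np.arange(2, 2 + n_harmonics)
    coeffs = rng.uniform(0.3, 1.0, size=n_harmonics) / np.sqrt(orders - 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    total = np.sum(np.abs(coeffs))
    if total > 0:
        coeffs = coeffs * (0.8 / total)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    wave = np.sum(coeffs[:, None] * np.cos(orders[:, None] * theta[None, :] + phases[:, None]), axis=0)
    r = base_radius * (1.0 + distortion * wave)
    if np.any(r <= 0):
        raise ValueError("parameters produce non-positive radius")
    cx, cy = center
    verts = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
    return Boundary(verts, closed=True)


def radial_profile(
    base_radius: float,
    distortion: float,
    n_harmonics: int,
    rng_seed: int,
    theta: np.ndarray,
) -> np.ndarray:
    """Evaluate the analytic ``r(theta)`` of :func:`generate_crypt_boundary`
    at arbitrary angles (same seeded coefficients)."""
    rng = np.random.default_rng(rng_seed)
    orders = np.arange(2, 2 + n_harmonics)
    coeffs = rng.uniform(0.3, 1.0, size=n_harmonics) / np.sqrt(orders - 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_harmonics)
    total = np.sum(np.abs(coeffs))
    if total > 0:
        coeffs = coeffs * (0.8 / total)
    wave = np.sum(coeffs[:, None] * np.cos(orders[:, None] * theta[None, :] + phases[:, None]), axis=0)
    return base_radius * (1.0 + distortion * wave)


def _illumination_field(width: int, height: int, rng: np.random.Generator,
                        amplitude: float = ILLUMINATION_AMPLITUDE) -> np.ndarray:
    """Smooth multiplicative illumination: low-order 2-D polynomial, max
    deviation exactly ``amplitude``."""
    u = np.linspace(-1.0, 1.0, width)[None, :]
    v = np.linspace(-1.0, 1.0, height)[:, None]
    c = rng.uniform(-1.0, 1.0, size=5)
    surf = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u * u + c[4] * v * v
    peak = np.max(np.abs(surf))
    if peak > 0:
        surf = surf / peak
    return 1.0 + amplitude * surf


def generate_biopsy_image(
    params: GradeParams,
    width: int = 800,
    height: int = 600,
    rng_seed: int = 0,
    base_radius: Optional[float] = None,
    return_illumination: bool = False,
):
    """Render one synthetic biopsy field and its exact ground truth.

    Crypts are laid out on a jittered grid above the muscularis band,
    bottom row first (the "first line of crypts"), with rejection sampling
    against overlap; crypts that cannot be placed are dropped and the actual
    count is what the ground truth records.
    """
    rng = np.random.default_rng(rng_seed)
    if base_radius is None:
        base_radius = max(8.0, round(min(width, height) / 24.0))
    band_h = max(12, height // 15)
    band_top = height - band_h

    n_target = int(rng.integers(params.crypt_count_range[0], params.crypt_count_range[1] + 1))
    r_max = base_radius * (1.0 + 0.8 * params.boundary_distortion)
    margin = r_max + 4.0

    usable_h = band_top - params.basal_gap - 2 * margin
    usable_w = width - 2 * margin
    if usable_h <= 0 or usable_w <= 2 * r_max:
        raise ValueError("image too small to host the requested crypt count")
    n_cols = max(1, int(math.ceil(math.sqrt(n_target * usable_w / max(usable_h, 1.0)))))
    n_rows = max(1, int(math.ceil(n_target / n_cols)))
    while n_rows * 2.4 * r_max > usable_h and n_cols < n_target:
        n_cols += 1
        n_rows = max(1, int(math.ceil(n_target / n_cols)))
    cell_w = usable_w / n_cols
    cell_h = usable_h / n_rows

    boundaries: List[Boundary] = []
    centroids: List[np.ndarray] = []
    centers: List[np.ndarray] = []
    placed = 0
    # bottom row first, then upward
    cells = [(row, col) for row in range(n_rows) for col in range(n_cols)]
    for row, col in cells:
        if placed >= n_target:
            break
        crypt_seed = int(rng.integers(0, 2**31 - 1))
        gap = params.basal_gap * (1.0 + params.gap_jitter * float(rng.uniform(-1.0, 1.0)))
        ok = False
        for _ in range(30):
            jx = params.spacing_jitter * cell_w * float(rng.uniform(-0.5, 0.5))
            jy = params.spacing_jitter * cell_h * float(rng.uniform(-0.5, 0.5))
            cx = margin + (col + 0.5) * cell_w + jx
            if row == 0:
                cy = band_top - gap - r_max
            else:
                cy = band_top - params.basal_gap - margin - (row + 0.5) * cell_h + jy
            cx = float(np.clip(cx, margin, width - margin))
            cy = float(np.clip(cy, margin, band_top - gap - r_max))
            c = np.array([cx, cy])
            if all(np.linalg.norm(c - o) > 2.2 * r_max for o in centers):
                ok = True
                break
        if not ok:
            continue  # unplaceable: reduce count, ground truth records actuals
        b = generate_crypt_boundary(base_radius, params.boundary_distortion,
                                    rng_seed=crypt_seed, center=(cx, cy))
        boundaries.append(b)
        centroids.append(polygon_centroid(b.vertices))
        centers.append(c)
        placed += 1

    # muscularis upper edge: gently wavy, spans the full width
    xs = np.arange(width, dtype=float)
    phase = float(rng.uniform(0, 2 * np.pi))
    edge_y = band_top + 3.0 * np.sin(2.0 * np.pi * xs / max(width / 2.5, 1.0) + phase)
    musc = Boundary(np.column_stack([xs, edge_y]), closed=False)

    img = np.full((height, width), STROMA_LEVEL, dtype=float)
    yy = np.arange(height, dtype=float)[:, None]
    img[yy >= edge_y[None, :]] = MUSCULARIS_LEVEL
    for b in boundaries:
        rr, cc = draw_polygon(b.y, b.x, shape=img.shape)
        img[rr, cc] = LUMEN_LEVEL
    img = ndimage.gaussian_filter(img, sigma=1.0)

    illum = _illumination_field(width, height, rng)
    img = img * illum
    img = img + rng.normal(0.0, NOISE_SIGMA, size=img.shape)
    img = np.clip(img, 0.0, 255.0).round().astype(np.uint8)

    truth = GroundTruth(
        crypt_boundaries=boundaries,
        crypt_centroids=np.array(centroids).reshape(-1, 2),
        muscularis_polyline=musc,
        grade=params.grade,
    )
    limg = LabeledImage(img, grade=params.grade,
                        source_id=f"synthetic-{params.grade.name}-{rng_seed}")
    if return_illumination:
        background = np.clip(STROMA_LEVEL * illum, 0.0, 255.0)
        return limg, truth, LabeledImage(background, source_id="background")
    return limg, truth


def generate_cohort(
    n_per_grade: int,
    rng_seed: int = 0,
    grade_params: Optional[Dict[Grade, GradeParams]] = None,
    width: int = 800,
    height: int = 600,
) -> List[Tuple[LabeledImage, GroundTruth]]:
    """Balanced cohort of ``4 * n_per_grade`` fields, seeds derived from
    ``rng_seed`` deterministically."""
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    gp = grade_params or DEFAULT_GRADE_PARAMS
    seeder = np.random.default_rng(rng_seed)
    out: List[Tuple[LabeledImage, GroundTruth]] = []
    for grade in GRADES:
        for _ in range(n_per_grade):
            seed = int(seeder.integers(0, 2**31 - 1))
            out.append(generate_biopsy_image(gp[grade], width=width, height=height,
                                             rng_seed=seed))
    return out


def ground_truth_to_json(truth: GroundTruth) -> dict:
    return {
        "grade": truth.grade.name,
        "crypt_boundaries": [b.vertices.tolist() for b in truth.crypt_boundaries],
        "crypt_centroids": truth.crypt_centroids.tolist(),
        "muscularis_polyline": truth.muscularis_polyline.vertices.tolist(),
    }


def ground_truth_from_json(doc: dict) -> GroundTruth:
    return GroundTruth(
        crypt_boundaries=[Boundary(np.array(v), closed=True) for v in doc["crypt_boundaries"]],
        crypt_centroids=np.array(doc["crypt_centroids"]).reshape(-1, 2),
        muscularis_polyline=Boundary(np.array(doc["muscularis_polyline"]), closed=False),
        grade=Grade.from_name(doc["grade"]),
    )


def write_cohort(outdir: str | Path, cohort: List[Tuple[LabeledImage, GroundTruth]]) -> None:
    """Write each field as PNG plus a JSON ground-truth sidecar."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, (img, truth) in enumerate(cohort):
        stem = f"{i:04d}_{truth.grade.name}"
        iio.imwrite(outdir / f"{stem}.png", img.pixels.astype(np.uint8))
        with open(outdir / f"{stem}.json", "w") as fh:
            json.dump(ground_truth_to_json(truth), fh)
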