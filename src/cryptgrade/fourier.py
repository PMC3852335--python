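"""Fourier shape descriptors of crypt outlines.

A crypt boundary is parametrized in polar form r(theta) about its centroid,
sampled at K equally spaced angles, and transformed with the K-point DFT

    z_u = (1/K) * sum_k r_k * exp(-2*pi*i*u*k/K),  u = 0..K-1.

Normalization follows the classic recipe: the 0th coefficient (position /
mean radius) is nullified, all magnitudes are divided by |z_1| for size
invariance, and phases are discarded for rotation invariance.  The nine
magnitudes |z_1|..|z_9| are the per-crypt shape features; a per-image shape
descriptor is their average over non-degenerate crypts.

Because the signature is taken about the area centroid, the first harmonic
of r(theta) cancels to first order in the distortion amplitude, so |z_1| is
small for near-symmetric outlines; an epsilon-guard flags those crypts as
degenerate (maximally regular) rather than dividing by noise.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Boundary, ContourSet, point_in_polygon

N_DESCRIPTORS = 9


@dataclass(frozen=True)
class RadialSignature:
    """K radii sampled at theta_k = 2*pi*k/K about a crypt centroid."""

    samples: np.ndarray
    K: int

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if len(s) != self.K:
            raise ValueError("sample count must equal K")
        if self.K < 16 or self.K % 2:
            raise ValueError("K must be even and >= 16")
        if np.any(s <= 0):
            raise ValueError("all radii must be positive")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class RawDescriptors:
    """The K complex DFT coefficients z_0..z_{K-1} of a radial signature."""

    coefficients: np.ndarray

    @property
    def K(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class DescriptorVector:
    """Normalized |z_1|..|z_9|; all-zero with the flag set when degenerate."""

    magnitudes: np.ndarray
    degenerate: bool = False


def radial_signature(boundary: Boundary, centroid: Sequence[float], K: int = 64) -> RadialSignature:
    """Sample r(theta) by exact ray-polygon intersection.

    For each angular bin the ray from the centroid is intersected with every
    polygon edge; the maximum crossing distance is taken, which keeps the
    signature single-valued for non-star-convex outlines.
    """
    if not boundary.closed:
        raise ValueError("radial signature requires a closed boundary")
    c = np.asarray(centroid, dtype=float)
    if not point_in_polygon(c, boundary.vertices):
        raise ValueError("centroid lies outside the boundary (segmentation failure?)")
    v = boundary.vertices - c
    theta = 2.0 * np.pi * np.arange(K) / K
    d = np.column_stack([np.cos(theta), np.sin(theta)])   # ray directions
    # signed perpendicular coordinate of every vertex w.r.t. each ray line;
    # an edge is crossed iff its endpoints fall in different half-open sign
    # classes (>= 0 vs < 0), which partitions crossings without gaps even
    # when the line passes through a vertex
    perp = d[:, 1:2] * v[None, :, 0] - d[:, 0:1] * v[None, :, 1]   # (K, n)
    along = d[:, 0:1] * v[None, :, 0] + d[:, 1:2] * v[None, :, 1]  # (K, n)
    perp_next = np.roll(perp, -1, axis=1)
    along_next = np.roll(along, -1, axis=1)
    crossed = (perp >= 0.0) != (perp_next >= 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = perp / (perp - perp_next)
    s = along + t * (along_next - along)
    valid = crossed & (s > 0.0)
    s = np.where(valid, s, -np.inf)
    r = s.max(axis=1)
    if np.any(~np.isfinite(r)) or np.any(r <= 0):
        raise ValueError("ray-polygon intersection failed; centroid not interior")
    return RadialSignature(r, K)


def dft(signature: RadialSignature) -> RawDescriptors:
    """K-point DFT with the 1/K factor (FFT of the real radius samples)."""
    z = np.fft.fft(signature.samples) / signature.K
    return RawDescriptors(z)


def inverse_dft(raw: RawDescriptors, n_pairs: Optional[int] = None) -> np.ndarray:
    """Reconstruct the radius samples, optionally truncating to the DC term
    plus the first ``n_pairs`` conjugate coefficient pairs."""
    z = np.array(raw.coefficients, dtype=complex)
    K = len(z)
    if n_pairs is not None:
        keep = np.zeros(K, dtype=bool)
        keep[0] = True
        for m in range(1, n_pairs + 1):
            keep[m] = True
            keep[K - m] = True
        z = np.where(keep, z, 0.0)
    return np.real(np.fft.ifft(z) * K)


def normalize_descriptors(raw: RawDescriptors) -> DescriptorVector:
    """Position, size and rotation normalization of the descriptors.

    z_0 is nullified and dropped, magnitudes are divided by |z_1|, phases
    discarded.  When |z_1| is below the epsilon-guard the crypt is flagged
    degenerate (maximally regular) and the zero vector returned.
    """
    z = raw.coefficients
    if len(z) < N_DESCRIPTORS + 1:
        raise ValueError("need at least 10 coefficients")
    mags = np.abs(z)
    eps = 1e-12 * mags[0] if mags[0] > 0 else 1e-12
    if mags[1] < eps:
        return DescriptorVector(np.zeros(N_DESCRIPTORS), degenerate=True)
    out = mags[1:N_DESCRIPTORS + 1] / mags[1]
    return DescriptorVector(out, degenerate=False)


def crypt_descriptors(boundary: Boundary, centroid: Sequence[float], K: int = 64) -> DescriptorVector:
    """Radial signature -> DFT -> normalized magnitudes for one crypt."""
    return normalize_descriptors(dft(radial_signature(boundary, centroid, K)))


@dataclass
class ImageShapeFeatures:
    """Per-image average of the non-degenerate crypt descriptor vectors."""

    values: np.ndarray
    n_crypts: int
    n_degenerate: int
    all_degenerate: bool


def image_shape_features(
    contours: ContourSet,
    K: int = 64,
    centroids: Optional[np.ndarray] = None,
) -> ImageShapeFeatures:
    """Component-wise mean DescriptorVector over the image's crypts.

    Degenerate crypts are excluded from the mean; with no usable crypt the
    zero vector is returned with the ``all_degenerate`` flag set.
    ``centroids`` may carry precomputed moment centroids (one per crypt);
    otherwise they are derived from the filled outlines.
    """
    from .mst import centroid_from_boundary

    vecs: List[np.ndarray] = []
    n_degenerate = 0
    for i, crypt in enumerate(contours.crypts):
        if centroids is not None:
            c = np.asarray(centroids[i], dtype=float)
        else:
            cc = centroid_from_boundary(crypt)
            c = np.array([cc.x, cc.y])
        dv = crypt_descriptors(crypt, c, K)
        if dv.degenerate:
            n_degenerate += 1
        else:
            vecs.append(dv.magnitudes)
    n = len(contours.crypts)
    if not vecs:
        return ImageShapeFeatures(np.zeros(N_DESCRIPTORS), n, n_degenerate, True)
    return ImageShapeFeatures(np.mean(vecs, axis=0), n, n_degenerate, False)
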