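"""Crypt-base-to-muscularis distance via first-order line fits.

A line y = a*x + b is fitted by ordinary least squares to the muscularis
edge vertices and another to the base points of the first row of crypts;
perpendicular norms from every muscularis vertex to the crypt line summarize
the basal gap.  The default feature is the mean norm divided by the image
diagonal (an absolute, scale-normalized gap); the mean/max-norm ratio is
also computed and available as an alternative normalization mode.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .geometry import Boundary, polygon_centroid


@dataclass(frozen=True)
class LineFit:
    """OLS fit y = a*x + b with its mean squared residual."""

    a: float
    b: float
    mse: float

    def y_at(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) + self.b

    def perpendicular_distance(self, points: np.ndarray) -> np.ndarray:
        """Point-to-line distances |a*x - y + b| / sqrt(a^2 + 1)."""
        p = np.asarray(points, dtype=float).reshape(-1, 2)
        return np.abs(self.a * p[:, 0] - p[:, 1] + self.b) / np.hypot(self.a, 1.0)


def fit_line(points: Sequence[Sequence[float]]) -> LineFit:
    """Closed-form ordinary least squares line through 2-D points."""
    p = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(p) < 2:
        raise ValueError("need at least two points")
    x, y = p[:, 0], p[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("all x equal: degenerate (vertical) orientation")
    a = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    b = float(y.mean() - a * x.mean())
    resid = y - (a * x + b)
    return LineFit(a, b, float(np.mean(resid ** 2)))


def crypt_base_points(crypts: Sequence[Boundary], muscularis_fit: LineFit) -> np.ndarray:
    """Base points of the first row of crypts.

    The first row consists of crypts whose centroid's perpendicular distance
    to the muscularis line is within 1.5x the minimum such distance; each
    selected crypt contributes its boundary vertex closest to that line.
    Falls back to the two nearest crypts when fewer than two qualify.
    """
    if len(crypts) < 2:
        raise ValueError("need at least two crypts")
    cents = np.array([polygon_centroid(c.vertices) for c in crypts])
    d = muscularis_fit.perpendicular_distance(cents)
    sel = np.where(d <= 1.5 * d.min())[0]
    if len(sel) < 2:
        sel = np.argsort(d, kind="stable")[:2]
    base = []
    for i in sel:
        dv = muscularis_fit.perpendicular_distance(crypts[i].vertices)
        base.append(crypts[i].vertices[int(np.argmin(dv))])
    return np.array(base)


@dataclass
class MuscularisFeature:
    """Basal-gap feature with the intermediate norms for audit."""

    value: float
    flagged: bool = False
    mean_norm: float = float("nan")
    max_norm: float = float("nan")
    ratio: float = float("nan")
    muscularis_fit: Optional[LineFit] = None
    crypt_fit: Optional[LineFit] = None


def muscularis_distance_feature(
    muscularis: Optional[Boundary],
    crypts: Sequence[Boundary],
    image_diag: float,
    mode: str = "scaled",
) -> MuscularisFeature:
    """Normalized crypt-base-to-muscularis distance in [0, 1].

    ``mode='scaled'`` (default): mean perpendicular norm / image diagonal.
    ``mode='ratio'``: mean norm / maximum norm encountered.
    A missing muscularis or fewer than two crypts saturates the feature at
    1.0 (severe-damage direction) with the flag set.
    """
    if mode not in ("scaled", "ratio"):
        raise ValueError("mode must be 'scaled' or 'ratio'")
    if muscularis is None or len(crypts) < 2:
        return MuscularisFeature(1.0, flagged=True)
    try:
        m_fit = fit_line(muscularis.vertices)
        base = crypt_base_points(crypts, m_fit)
        c_fit = fit_line(base)
    except ValueError:
        return MuscularisFeature(1.0, flagged=True)
    norms = c_fit.perpendicular_distance(muscularis.vertices)
    mean_norm, max_norm = float(norms.mean()), float(norms.max())
    ratio = 1.0 if max_norm == 0.0 else mean_norm / max_norm
    if mode == "ratio":
        value = ratio
    else:
        value = mean_norm / float(image_diag)
    return MuscularisFeature(min(value, 1.0), False, mean_norm, max_norm, ratio, m_fit, c_fit)
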