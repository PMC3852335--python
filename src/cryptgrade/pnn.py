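"""Probabilistic neural network (Parzen-window Bayes classifier).

The PNN stores every training pattern verbatim (one hidden node each) and
estimates the class-conditional density with a Gaussian kernel of shared
width sigma,

    f_i(v) = (1/n_i) * sum_{w in class i} exp(-||v - w||^2 / (2*sigma^2)),

on min-max-scaled features.  A vector is assigned to the class maximizing
p_i * L_i * f_i(v) (prior x misclassification loss x density); exact ties
break toward the lower severity grade.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grades import GRADES, Grade

FORMAT_VERSION = 1


@dataclass
class PNNModel:
    """Stored training patterns, kernel width, priors, losses and scaler."""

    patterns: Dict[Grade, np.ndarray]   # class -> (n_i, d) scaled patterns
    sigma: float
    priors: Dict[Grade, float]
    losses: Dict[Grade, float]
    scaler_min: np.ndarray
    scaler_max: np.ndarray

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        total = sum(self.priors.values())
        if not np.isclose(total, 1.0):
            raise ValueError("priors must sum to 1")
        if any(l <= 0 for l in self.losses.values()):
            raise ValueError("losses must be positive")

    @property
    def classes(self) -> List[Grade]:
        return sorted(self.patterns.keys())

    @property
    def n_features(self) -> int:
        return next(iter(self.patterns.values())).shape[1]

    def scale(self, v: np.ndarray) -> np.ndarray:
        """Min-max scale with the training extremes; values clipped to
        [-0.5, 1.5] on the scaled axis to bound extrapolation."""
        v = np.asarray(v, dtype=float)
        rng = self.scaler_max - self.scaler_min
        out = np.zeros_like(v)
        ok = rng > 0
        out[..., ok] = (v[..., ok] - self.scaler_min[ok]) / rng[ok]
        return np.clip(out, -0.5, 1.5)


def train(
    features: Sequence[Sequence[float]],
    labels: Sequence[Grade],
    sigma: float = 0.1,
    priors_mode: str = "empirical",
    losses: Optional[Dict[Grade, float]] = None,
) -> PNNModel:
    """Fit the min-max scaler and store the scaled patterns per class.

    The PNN has no iterative weight fitting: training is scaling plus
    verbatim pattern storage and prior estimation.
    """
    X = np.asarray(features, dtype=float)
    y = list(labels)
    if len(X) != len(y):
        raise ValueError("features and labels must have equal length")
    present = sorted(set(y))
    if len(present) < 2:
        raise ValueError("need examples of at least two classes")
    fmin = X.min(axis=0)
    fmax = X.max(axis=0)
    if np.any(fmax == fmin):
        warnings.warn("degenerate feature(s) with max == min scaled to 0", stacklevel=2)
    rng = fmax - fmin
    Xs = np.zeros_like(X)
    ok = rng > 0
    Xs[:, ok] = (X[:, ok] - fmin[ok]) / rng[ok]
    patterns = {g: Xs[np.array([yy == g for yy in y])] for g in present}
    n = len(y)
    if priors_mode == "empirical":
        priors = {g: len(patterns[g]) / n for g in present}
    elif priors_mode == "uniform":
        priors = {g: 1.0 / len(present) for g in present}
    else:
        raise ValueError("priors_mode must be 'empirical' or 'uniform'")
    losses = dict(losses) if losses else {g: 1.0 for g in present}
    return PNNModel(patterns, float(sigma), priors, losses, fmin, fmax)


def class_density(model: PNNModel, v: Sequence[float], grade: Grade) -> float:
    """Parzen-window Gaussian kernel density f_i(v) for one class."""
    if grade not in model.patterns:
        raise ValueError(f"class {grade!r} not represented in the model")
    vs = model.scale(np.asarray(v, dtype=float))
    w = model.patterns[grade]
    d2 = np.sum((w - vs) ** 2, axis=1)
    return float(np.mean(np.exp(-d2 / (2.0 * model.sigma ** 2))))


def classify(model: PNNModel, v: Sequence[float]) -> Tuple[Grade, Dict[Grade, float]]:
    """Bayes decision: argmax of p_i * L_i * f_i(v); ties -> lower grade.

    When every score underflows to zero (sigma far too small) the decision
    falls back to the nearest stored pattern, with a warning.
    """
    scores = {g: model.priors[g] * model.losses[g] * class_density(model, v, g)
              for g in model.classes}
    best = max(scores.values())
    if best <= 0.0:
        warnings.warn("all class scores underflowed; falling back to nearest pattern",
                      stacklevel=2)
        vs = model.scale(np.asarray(v, dtype=float))
        nearest, nd = None, np.inf
        for g in model.classes:
            d2 = np.sum((model.patterns[g] - vs) ** 2, axis=1)
            if d2.min() < nd:
                nd, nearest = float(d2.min()), g
        return nearest, scores
    for g in model.classes:  # ascending grade order -> ties go to lower grade
        if scores[g] == best:
            return g, scores
    raise AssertionError("unreachable")


def loo_accuracy(features: np.ndarray, labels: Sequence[Grade], sigma: float,
                 priors_mode: str = "empirical") -> float:
    """Leave-one-out training-set accuracy at a given kernel width."""
    X = np.asarray(features, dtype=float)
    y = list(labels)
    n = len(y)
    fmin, fmax = X.min(axis=0), X.max(axis=0)
    rng = fmax - fmin
    Xs = np.zeros_like(X)
    ok = rng > 0
    Xs[:, ok] = (X[:, ok] - fmin[ok]) / rng[ok]
    d2 = np.sum((Xs[:, None, :] - Xs[None, :, :]) ** 2, axis=2)
    kern = np.exp(-d2 / (2.0 * sigma ** 2))
    np.fill_diagonal(kern, 0.0)
    classes = sorted(set(y))
    yarr = np.array([int(g) for g in y])
    correct = 0
    for i in range(n):
        best_g, best_s = None, -np.inf
        for g in classes:
            mask = yarr == int(g)
            n_g = int(mask.sum()) - (1 if yarr[i] == int(g) else 0)
            if n_g == 0:
                continue
            dens = float(kern[i, mask].sum()) / n_g
            prior = n_g / (n - 1) if priors_mode == "empirical" else 1.0 / len(classes)
            s = prior * dens
            if s > best_s:
                best_s, best_g = s, g
        if best_g is not None and int(best_g) == yarr[i]:
            correct += 1
    return correct / n


def select_sigma(
    features: Sequence[Sequence[float]],
    labels: Sequence[Grade],
    grid: Sequence[float],
) -> float:
    """Kernel width maximizing leave-one-out accuracy; ties -> smallest."""
    if len(grid) == 0:
        raise ValueError("grid must be non-empty")
    X = np.asarray(features, dtype=float)
    best_sigma, best_acc = None, -1.0
    for s in sorted(float(s) for s in grid):
        acc = loo_accuracy(X, labels, s)
        if acc > best_acc + 1e-12:
            best_acc, best_sigma = acc, s
    return best_sigma


def save_model(model: PNNModel, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "sigma": model.sigma,
        "priors": {g.name: p for g, p in model.priors.items()},
        "losses": {g.name: l for g, l in model.losses.items()},
        "scaler_min": model.scaler_min.tolist(),
        "scaler_max": model.scaler_max.tolist(),
        "patterns": {g.name: w.tolist() for g, w in model.patterns.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> PNNModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    return PNNModel(
        patterns={Grade[g]: np.array(w, dtype=float) for g, w in doc["patterns"].items()},
        sigma=float(doc["sigma"]),
        priors={Grade[g]: float(p) for g, p in doc["priors"].items()},
        losses={Grade[g]: float(l) for g, l in doc["losses"].items()},
        scaler_min=np.array(doc["scaler_min"], dtype=float),
        scaler_max=np.array(doc["scaler_max"], dtype=float),
    )
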