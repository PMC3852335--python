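"""End-to-end orchestration: image -> 11 features -> grade, plus dataset
splitting and precision/recall evaluation against reference labels.

The per-image feature vector is
``[fd1..fd9, mst_spacing, musc_distance]``: nine averaged Fourier-descriptor
magnitudes, the normalized mean inter-crypt MST spacing, and the normalized
crypt-base-to-muscularis distance.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fourier import image_shape_features
from .geometry import ContourSet
from .grades import GRADES, Grade
from .mst import centroid_from_boundary, crypt_spacing_feature
from .pnn import PNNModel, classify
from .regression import muscularis_distance_feature
from .segmentation import SnakeConfig, segment_biopsy
from .synthetic import LabeledImage

FEATURE_NAMES = [f"fd{i}" for i in range(1, 10)] + ["mst_spacing", "musc_distance"]
N_FEATURES = 11


@dataclass
class PipelineConfig:
    """All tunable parameters of the image-to-features pipeline."""

    snake: SnakeConfig = field(default_factory=SnakeConfig)
    fourier_K: int = 64
    spacing_mode: str = "mst_edge"
    distance_mode: str = "scaled"
    median_radius: int = 2
    background_radius: int = 60
    min_area: Optional[float] = None
    max_area: Optional[float] = None


@dataclass
class QCRecord:
    """Per-image quality-control flags and provenance."""

    source_id: str = ""
    n_crypts: int = 0
    n_degenerate: int = 0
    all_degenerate: bool = False
    sparse: bool = False
    muscularis_missing: bool = False
    unreadable: bool = False
    warnings: List[str] = field(default_factory=list)


def features_from_contours(contours: ContourSet, image_shape: Tuple[int, int],
                           config: Optional[PipelineConfig] = None,
                           source_id: str = "") -> Tuple[np.ndarray, QCRecord]:
    """Compute the 11-feature vector from an already-segmented contour set.

    Useful for running the feature stack directly on ground-truth contours.
    """
    cfg = config or PipelineConfig()
    qc = QCRecord(source_id=source_id, n_crypts=len(contours.crypts))
    h, w = image_shape
    diag = math.hypot(h, w)
    if not contours.crypts:
        qc.unreadable = True
        qc.sparse = True
        qc.muscularis_missing = contours.muscularis is None
        qc.warnings.append("no crypts detected: sentinel feature vector")
        return np.concatenate([np.zeros(9), [1.0, 1.0]]), qc
    cents = np.array([centroid_from_boundary(c).point for c in contours.crypts])
    shape = image_shape_features(contours, K=cfg.fourier_K, centroids=cents)
    qc.n_degenerate = shape.n_degenerate
    qc.all_degenerate = shape.all_degenerate
    spacing = crypt_spacing_feature(cents, mode=cfg.spacing_mode)
    qc.sparse = spacing.sparse
    dist = muscularis_distance_feature(contours.muscularis, contours.crypts, diag,
                                       mode=cfg.distance_mode)
    qc.muscularis_missing = contours.muscularis is None
    if dist.flagged:
        qc.warnings.append("muscularis distance flagged (missing edge or < 2 crypts)")
    vec = np.concatenate([shape.values, [spacing.value, dist.value]])
    return vec, qc


def extract_features(
    image: LabeledImage,
    background: Optional[LabeledImage] = None,
    config: Optional[PipelineConfig] = None,
) -> Tuple[np.ndarray, QCRecord]:
    """Segment the image and compute its 11 normalized features."""
    cfg = config or PipelineConfig()
    contours = segment_biopsy(image, background, config=cfg.snake,
                              min_area=cfg.min_area, max_area=cfg.max_area,
                              median_radius=cfg.median_radius,
                              background_radius=cfg.background_radius)
    return features_from_contours(contours, image.pixels.shape, cfg, image.source_id)


def split_dataset(
    cases: Sequence[Tuple[object, Grade]],
    train_fraction: float,
    seed: int,
) -> Tuple[List[Tuple[object, Grade]], List[Tuple[object, Grade]]]:
    """Deterministic stratified-by-grade split.

    Per-class training sizes follow largest-remainder rounding of
    ``train_fraction * n_class`` so class totals add up to
    ``round(train_fraction * n)``; a class with fewer than two cases goes
    entirely to training (with a warning).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    by_class: Dict[Grade, List[int]] = {}
    for idx, (_, g) in enumerate(cases):
        by_class.setdefault(g, []).append(idx)
    small = {g for g, idxs in by_class.items() if len(idxs) < 2}
    if small:
        warnings.warn(f"classes with < 2 cases assigned wholly to training: "
                      f"{sorted(g.name for g in small)}", stacklevel=2)
    eligible = [g for g in sorted(by_class) if g not in small]
    n_eligible = sum(len(by_class[g]) for g in eligible)
    target = int(round(train_fraction * n_eligible))
    raw = {g: train_fraction * len(by_class[g]) for g in eligible}
    base = {g: int(math.floor(raw[g] + 1e-9)) for g in eligible}
    leftover = target - sum(base.values())
    order = sorted(eligible, key=lambda g: (-(raw[g] - base[g]), int(g)))
    for g in order[:max(leftover, 0)]:
        base[g] += 1
    train_idx: List[int] = []
    for g in sorted(by_class):
        idxs = list(by_class[g])
        if g in small:
            train_idx.extend(idxs)
            continue
        perm = rng.permutation(len(idxs))
        take = min(base[g], len(idxs) - 0)
        train_idx.extend(idxs[i] for i in perm[:take])
    train_set = set(train_idx)
    train = [cases[i] for i in sorted(train_set)]
    test = [cases[i] for i in range(len(cases)) if i not in train_set]
    return train, test


@dataclass
class ConfusionMatrix:
    """counts[i, j]: reference grade i classified as grade j."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (4, 4) or np.any(c < 0):
            raise ValueError("confusion matrix must be 4x4 non-negative")
        self.counts = c

    @classmethod
    def from_pairs(cls, reference: Sequence[Grade], predictions: Sequence[Grade]) -> "ConfusionMatrix":
        if len(reference) != len(predictions):
            raise ValueError("predictions and reference must have equal length")
        c = np.zeros((4, 4), dtype=int)
        for r, p in zip(reference, predictions):
            c[int(r), int(p)] += 1
        return cls(c)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class EvaluationReport:
    """Precision/recall per grade plus the micro-averaged overall precision.

    Per-class precision uses the classifier-column denominator (correct
    over all cases classified into the grade); recall the reference-row
    denominator; a zero denominator yields None (undefined) and is excluded
    from any macro summary.
    """

    confusion: ConfusionMatrix
    precision: Dict[Grade, Optional[float]]
    recall: Dict[Grade, Optional[float]]
    overall_precision: float
    n_cases: int

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "precision": {g.name: self.precision[g] for g in GRADES},
            "recall": {g.name: self.recall[g] for g in GRADES},
            "overall_precision": self.overall_precision,
            "n_cases": self.n_cases,
        }

    def __str__(self) -> str:
        lines = ["grade     precision   recall"]
        for g in GRADES:
            p = self.precision[g]
            r = self.recall[g]
            ps = "  n/a " if p is None else f"{100*p:6.2f}%"
            rs = "  n/a " if r is None else f"{100*r:6.2f}%"
            lines.append(f"{g.label:<9} {ps}    {rs}")
        lines.append(f"overall   {100*self.overall_precision:6.2f}%   (n={self.n_cases})")
        return "\n".join(lines)


def evaluate_confusion(confusion: ConfusionMatrix) -> EvaluationReport:
    """Precision/recall arithmetic on a prebuilt confusion matrix."""
    c = confusion.counts
    total = int(c.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    precision: Dict[Grade, Optional[float]] = {}
    recall: Dict[Grade, Optional[float]] = {}
    for g in GRADES:
        col = int(c[:, int(g)].sum())
        row = int(c[int(g), :].sum())
        precision[g] = (int(c[int(g), int(g)]) / col) if col else None
        recall[g] = (int(c[int(g), int(g)]) / row) if row else None
    overall = float(np.trace(c)) / total
    return EvaluationReport(confusion, precision, recall, overall, total)


def evaluate(predictions: Sequence[Grade], reference: Sequence[Grade]) -> EvaluationReport:
    """Build the confusion matrix from paired labels and evaluate it."""
    return evaluate_confusion(ConfusionMatrix.from_pairs(reference, predictions))


@dataclass
class GradingResult:
    grade: Optional[Grade]
    features: np.ndarray
    qc: QCRecord
    scores: Dict[Grade, float] = field(default_factory=dict)
    unreadable: bool = False


def grade_biopsy(
    image: LabeledImage,
    model: PNNModel,
    config: Optional[PipelineConfig] = None,
    background: Optional[LabeledImage] = None,
) -> GradingResult:
    """Extract features and classify; hard extraction failures surface as an
    unreadable-case status, never a silent grade."""
    vec, qc = extract_features(image, background, config)
    if qc.unreadable:
        return GradingResult(None, vec, qc, unreadable=True)
    grade, scores = classify(model, vec)
    return GradingResult(grade, vec, qc, scores=scores)
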