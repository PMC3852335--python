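"""Severity grades and grade-dependent simulation parameters.

Chronic inflammatory bowel disease distorts the colonic mucosa: crypts lose
their straight tubular profile, crypt density drops, and the crypt bases pull
away from the muscularis mucosa.  Severity is graded Normal / I / II / III
(none, mild, moderate, severe architectural distortion).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple


class Grade(enum.IntEnum):
    """Architectural-distortion grade; the integer value is the severity ordinal."""

    NORMAL = 0
    I = 1
    II = 2
    III = 3

    @property
    def label(self) -> str:
        return {0: "Normal", 1: "Grade I", 2: "Grade II", 3: "Grade III"}[int(self)]

    @classmethod
    def from_name(cls, name: str) -> "Grade":
        key = name.strip().upper().replace("GRADE ", "").replace("GRADE_", "")
        aliases = {"NORMAL": cls.NORMAL, "0": cls.NORMAL,
                   "I": cls.I, "1": cls.I,
                   "II": cls.II, "2": cls.II,
                   "III": cls.III, "3": cls.III}
        if key not in aliases:
            raise ValueError(f"unknown grade name: {name!r}")
        return aliases[key]


GRADES: Tuple[Grade, ...] = (Grade.NORMAL, Grade.I, Grade.II, Grade.III)


@dataclass(frozen=True)
class GradeParams:
    """Simulation parameters of one severity grade.

    Attributes
    ----------
    grade:
        The severity grade these parameters emulate.
    boundary_distortion:
        Dimensionless amplitude in [0, 1] of the harmonic perturbation added
        to the crypt radius; larger values produce more irregular outlines.
    crypt_count_range:
        Inclusive (lo, hi) interval for the number of crypts per field;
        density decreases with severity.
    spacing_jitter:
        Fraction of the nominal grid spacing used to jitter crypt centres.
    basal_gap:
        Nominal distance, in pixels, between the crypt base and the
        muscularis mucosa; increases with severity.
    gap_jitter:
        Fractional jitter applied per-crypt to ``basal_gap``.
    """

    grade: Grade
    boundary_distortion: float
    crypt_count_range: Tuple[int, int]
    spacing_jitter: float
    basal_gap: float
    gap_jitter: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.boundary_distortion <= 1.0:
            raise ValueError("boundary_distortion must lie in [0, 1]")
        lo, hi = self.crypt_count_range
        if not (1 <= lo <= hi):
            raise ValueError("crypt_count_range must be a positive interval")
        if self.basal_gap <= 0:
            raise ValueError("basal_gap must be positive")


#: Default per-grade simulation parameters.  Distortion amplitude and basal
#: gap increase, and crypt count decreases, monotonically with severity.
DEFAULT_GRADE_PARAMS = {
    Grade.NORMAL: GradeParams(Grade.NORMAL, 0.03, (18, 24), 0.05, 15.0, 0.15),
    Grade.I: GradeParams(Grade.I, 0.15, (12, 18), 0.15, 25.0, 0.15),
    Grade.II: GradeParams(Grade.II, 0.35, (8, 12), 0.30, 40.0, 0.15),
    Grade.III: GradeParams(Grade.III, 0.60, (4, 8), 0.45, 60.0, 0.15),
}
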