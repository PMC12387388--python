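"""Stenosis severity grading from the maximum mitral valve area (MVA).

The planimetric cutoffs partition the non-negative areas into four
grades::

    no stenosis   a >= 4.0 cm²
    mild          1.5 < a < 4.0 cm²
    moderate      1.0 <= a <= 1.5 cm²
    severe        a < 1.0 cm²

The boundary conventions matter clinically: 4.0 cm² is *not* stenotic,
and both 1.0 and 1.5 cm² are moderate.  A bundled reference cohort of
30 transesophageal exams with planimetric MVA measurements ships with
the package for demonstrations and regression checks.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

from .errors import ValidationError


class StenosisGrade(str, Enum):
    NO_STENOSIS = "no_stenosis"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @property
    def has_stenosis(self) -> bool:
        return self is not StenosisGrade.NO_STENOSIS


#: Display order, least to most severe.
GRADE_ORDER: tuple[StenosisGrade, ...] = (
    StenosisGrade.NO_STENOSIS,
    StenosisGrade.MILD,
    StenosisGrade.MODERATE,
    StenosisGrade.SEVERE,
)


def classify_mva(area_cm2: float) -> StenosisGrade:
    """Map an MVA in cm² to its severity grade."""
    if area_cm2 < 0:
        raise ValidationError(f"area must be non-negative, got {area_cm2}")
    if area_cm2 >= 4.0:
        return StenosisGrade.NO_STENOSIS
    if area_cm2 > 1.5:
        return StenosisGrade.MILD
    if area_cm2 >= 1.0:
        return StenosisGrade.MODERATE
    return StenosisGrade.SEVERE


@dataclass(frozen=True)
class CohortSummary:
    """Per-grade counts and fractions for a set of exams."""

    n: int
    counts: dict[StenosisGrade, int]
    fractions: dict[StenosisGrade, float]

    def percentages(self, ndigits: int = 1) -> dict[StenosisGrade, float]:
        """Fractions as percentages rounded to ``ndigits`` decimals."""
        return {g: round(100.0 * f, ndigits) for g, f in self.fractions.items()}


def summarize_cohort(areas: Iterable[float]) -> CohortSummary:
    """Grade every area and tally counts and fractions per grade."""
    areas = list(areas)
    if not areas:
        raise ValidationError("cohort must contain at least one exam")
    tally = Counter(classify_mva(a) for a in areas)
    n = len(areas)
    counts = {g: tally.get(g, 0) for g in GRADE_ORDER}
    fractions = {g: counts[g] / n for g in GRADE_ORDER}
    return CohortSummary(n=n, counts=counts, fractions=fractions)


def reference_cohort_mva() -> list[float]:
    """The bundled 30-exam reference cohort of MVA values, in cm²."""
    path = resources.files("planim.data").joinpath("reference_cohort_mva.csv")
    with path.open() as fh:
        return [float(row["mva_cm2"]) for row in csv.DictReader(fh)]


def load_areas_csv(path: str) -> list[float]:
    """Read MVA values from a CSV with an ``mva_cm2`` column (or one column)."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r]
    if not rows:
        raise ValidationError(f"{path}: no rows")
    header = rows[0]
    if "mva_cm2" in header:
        col = header.index("mva_cm2")
        rows = rows[1:]
    else:
        col = 0
        try:
            float(header[0])
        except ValueError:
            rows = rows[1:]
    return [float(r[col]) for r in rows]
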