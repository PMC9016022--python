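"""IDDA2.1 total score, component breakdown, and longitudinal operations.

The per-visit total is

    total = (sum(lines 1..14) + H(line16) + I(line17) + sum(lines 18..21)) * M(line15)

with a capped hospitalization term ``H(d) = 0.1 d`` for ``d < 40`` else 4,
a capped intensive-care term ``I(d) = 0.8 d`` for ``d < 10`` else 8, and a
performance-scale multiplier ``M(k) = 150 / k`` for ``k > 29`` else 6
(Karnofsky/Lansky percent; the floor keeps the multiplier finite and
bounded at 6 for moribund patients). All three branch conditions are
strict, exactly as in the published spreadsheet formula. The attainable
range is 0 to (56 + 4 + 8 + 15) x 6 = 498. A malignancy is carried on the
breakdown as a flag but never contributes points.
"""

from __future__ import annotations

import datetime
import enum
import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .data_model import (
    N_ORGAN_ITEMS,
    VisitRecord,
    error_findings,
    igg_numeric,
    missing_lines,
)

__all__ = [
    "MAX_TOTAL",
    "MissingPolicy",
    "ScoreBreakdown",
    "TrajectoryPoint",
    "PhaseDelta",
    "InvalidRecordError",
    "MissingDataError",
    "TrajectoryError",
    "hosp_term",
    "icu_term",
    "performance_multiplier",
    "compute_score",
    "score_trajectory",
    "trajectory_summary",
    "phase_delta",
]

#: Maximum attainable total: (14*4 + 4 + 8 + (3+4+4+4)) * 6.
MAX_TOTAL = 498.0


class MissingPolicy(enum.Enum):
    """How to treat items marked missing when scoring.

    ``REFUSE`` (default) raises :class:`MissingDataError`; ``ZERO`` imputes
    missing items as 0, which makes the resulting total a lower bound.
    """

    REFUSE = "refuse"
    ZERO = "zero"


class InvalidRecordError(ValueError):
    """The record has validation errors and cannot be scored."""

    def __init__(self, findings):
        self.findings = list(findings)
        super().__init__(
            "record fails validation: " + "; ".join(f.message for f in self.findings)
        )


class MissingDataError(ValueError):
    """Missing items under the ``refuse`` policy."""

    def __init__(self, lines: Sequence[int]):
        self.lines = list(lines)
        super().__init__(
            f"items missing on lines {self.lines}; re-run with the "
            "missing-as-zero policy to score anyway (totals become lower bounds)"
        )


class TrajectoryError(ValueError):
    """Inconsistent visit series (mixed patients or duplicate dates)."""


def hosp_term(days: float) -> float:
    """Hospitalization contribution (line 16): ``0.1 * days``, capped at 4.

    ``days`` counts non-ICU hospital days out of the last 100; the cap is
    reached at 40 days and the two branches agree there, so the term is
    continuous.
    """
    if not 0 <= days <= 100:
        raise ValueError(f"hospitalization days (line 16) must be in [0, 100], got {days!r}")
    return days * 0.1 if days < 40 else 4.0


def icu_term(days: float) -> float:
    """ICU / mechanical-ventilation contribution (line 17): ``0.8 * days``, capped at 8."""
    if not 0 <= days <= 100:
        raise ValueError(f"ICU days (line 17) must be in [0, 100], got {days!r}")
    return days * 0.8 if days < 10 else 8.0


def performance_multiplier(kps: float) -> float:
    """Performance-scale factor (line 15): ``150 / kps``, floored at 6.

    For Karnofsky/Lansky values above 29 the factor is ``150 / kps``
    (1.5 at 100%, 5.0 at 30%); at 29% and below it is fixed at 6, so very
    low performance cannot inflate the score without bound.
    """
    if not 10 <= kps <= 100:
        raise ValueError(f"performance scale (line 15) must be in [10, 100], got {kps!r}")
    return 150.0 / kps if kps > 29 else 6.0


@dataclass(frozen=True)
class ScoreBreakdown:
    """Components of one visit's IDDA2.1 total."""

    organ_sum: int
    hosp_term: float
    icu_term: float
    supportive_sum: int
    multiplier: float
    total: float
    malignancy_flag: bool

    def as_dict(self) -> dict:
        return {
            "organ_sum": self.organ_sum,
            "hosp_term": self.hosp_term,
            "icu_term": self.icu_term,
            "supportive_sum": self.supportive_sum,
            "multiplier": self.multiplier,
            "total": self.total,
            "malignancy_flag": self.malignancy_flag,
        }


def _value_or_policy(value, missing_policy: MissingPolicy):
    if value is None:
        return 0 if missing_policy is MissingPolicy.ZERO else None
    return value


def compute_score(
    record: VisitRecord,
    missing_policy: MissingPolicy | str = MissingPolicy.REFUSE,
) -> ScoreBreakdown:
    """Evaluate the IDDA2.1 formula for one visit.

    Parameters
    ----------
    record
        A visit record; it must have no validation errors
        (warnings, such as a non-decile performance value, are fine).
    missing_policy
        ``"refuse"`` (default) raises :class:`MissingDataError` if any
        scorable item is marked missing; ``"zero"`` scores missing items
        as 0, yielding a lower bound on the true total.

    Returns
    -------
    ScoreBreakdown
        All formula components and the total. The malignancy flag is
        copied onto the breakdown but never added to the total.
    """
    missing_policy = MissingPolicy(missing_policy)
    errors = error_findings(record)
    if errors:
        raise InvalidRecordError(errors)
    missing = missing_lines(record)
    if missing and missing_policy is MissingPolicy.REFUSE:
        raise MissingDataError(missing)

    organ_sum = sum(g or 0 for g in record.organ_grades)
    h = hosp_term(record.hospital_days_per_100)
    i = icu_term(record.icu_days_per_100)
    supportive_sum = (
        igg_numeric(record.igg_substitution)
        + (record.chronic_infestation or 0)
        + (record.other_organ_dysfunction or 0)
        + (record.nutrition_status or 0)
    )
    m = performance_multiplier(record.performance_scale)
    total = (organ_sum + h + i + supportive_sum) * m
    return ScoreBreakdown(
        organ_sum=organ_sum,
        hosp_term=h,
        icu_term=i,
        supportive_sum=supportive_sum,
        multiplier=m,
        total=total,
        malignancy_flag=record.malignancy,
    )


@dataclass(frozen=True)
class TrajectoryPoint:
    visit_date: datetime.date
    therapy_phase: Optional[str]
    breakdown: ScoreBreakdown


def score_trajectory(
    visits: Sequence[VisitRecord],
    missing_policy: MissingPolicy | str = MissingPolicy.REFUSE,
) -> list[TrajectoryPoint]:
    """Score a patient's visit series in chronological order.

    The result is sorted by visit date ascending and is therefore stable
    under permutation of the input. All visits must belong to the same
    patient and carry distinct dates.
    """
    if not visits:
        raise TrajectoryError("empty visit series")
    ids = {v.patient_id for v in visits}
    if len(ids) > 1:
        raise TrajectoryError(f"visits mix patient ids: {sorted(ids)}")
    dates = [v.visit_date for v in visits]
    if len(set(dates)) != len(dates):
        dupes = sorted({d for d in dates if dates.count(d) > 1})
        raise TrajectoryError(f"duplicate visit dates: {[d.isoformat() for d in dupes]}")
    ordered = sorted(visits, key=lambda v: v.visit_date)
    return [
        TrajectoryPoint(v.visit_date, v.therapy_phase, compute_score(v, missing_policy))
        for v in ordered
    ]


def trajectory_summary(points: Sequence[TrajectoryPoint]) -> str:
    """Classify a trajectory: ``improving``, ``worsening``, ``stable`` or ``mixed``.

    Comparisons between consecutive totals are strict; a single visit is
    ``stable``. A series with both strict rises and strict falls is
    ``mixed``.
    """
    totals = [p.breakdown.total for p in points]
    deltas = [b - a for a, b in zip(totals, totals[1:])]
    if not deltas or all(d == 0 for d in deltas):
        return "stable"
    if all(d <= 0 for d in deltas):
        return "improving"
    if all(d >= 0 for d in deltas):
        return "worsening"
    return "mixed"


@dataclass(frozen=True)
class PhaseDelta:
    """Mean per-item and total-score change between two therapy phases.

    ``item_deltas`` maps each item line (1-22) to ``mean(phase_b) -
    mean(phase_a)`` of that item's numeric value; means are taken over
    visits where the item is not missing, ``math.nan`` if an item is
    missing from every visit of a phase. Line 18 is compared on its points
    scale (0/2/3) and line 22 as 0/1.
    """

    phase_a: str
    phase_b: str
    item_deltas: dict[int, float]
    total_delta: float


def phase_delta(
    visits: Sequence[VisitRecord],
    phase_a: str,
    phase_b: str,
    missing_policy: MissingPolicy | str = MissingPolicy.ZERO,
) -> PhaseDelta:
    """Compare mean item grades and totals between two therapy phases.

    Used to summarize the effect of a therapeutic measure (e.g. before vs
    after starting sirolimus, or pre- vs post-HSCT) across one or many
    patients' visits. The default missing policy for the total is
    missing-as-zero, since phase comparisons are typically run on partially
    documented retrospective charts.
    """
    groups = {phase_a: [], phase_b: []}
    for v in visits:
        if v.therapy_phase in groups:
            groups[v.therapy_phase].append(v)
    for label, group in groups.items():
        if not group:
            raise KeyError(f"no visits in therapy phase {label!r}")

    def phase_mean(group: Sequence[VisitRecord], line: int) -> float:
        vals = [v.line_value(line) for v in group]
        vals = [x for x in vals if x is not None]
        return statistics.fmean(vals) if vals else math.nan

    item_deltas = {
        line: phase_mean(groups[phase_b], line) - phase_mean(groups[phase_a], line)
        for line in range(1, 23)
    }
    mean_totals = {
        label: statistics.fmean(
            compute_score(v, missing_policy).total for v in group
        )
        for label, group in groups.items()
    }
    return PhaseDelta(
        phase_a=phase_a,
        phase_b=phase_b,
        item_deltas=item_deltas,
        total_delta=mean_totals[phase_b] - mean_totals[phase_a],
    )
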