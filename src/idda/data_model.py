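"""The 22-item IDDA2.1 visit record and its grading rubrics.

One :class:`VisitRecord` captures a single clinical assessment of a patient
with an inborn error of immunity (IEI): fourteen organ/feature items graded
0-4 for severity of immune dysregulation, the Karnofsky/Lansky performance
scale, hospitalization and intensive-care day counts over a 100-day window,
supportive-care items (immunoglobulin substitution, chronic infestation,
other organ dysfunction, nutrition status), and a malignancy flag that is
documented but never enters the numeric score.

Grading rubric for the fourteen organ items (lines 1-14):

====== =====================================================
grade  meaning
====== =====================================================
0      absent
1      mild, transient, not requiring treatment
2      moderate, intermittent therapy needed
3      severe, continuous therapy needed
4      life-threatening, refractory, irreversible
====== =====================================================

Validation is data, not control flow: :func:`validate_visit` returns a list
of :class:`Finding` objects, one per violated rule, each naming the
offending item line; it raises nothing.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field, fields, replace
from typing import Any, Optional, Sequence

__all__ = [
    "N_ORGAN_ITEMS",
    "ORGAN_LABELS",
    "LINE_LABELS",
    "IggSubstitution",
    "igg_numeric",
    "InvalidCodeError",
    "VisitRecord",
    "Finding",
    "validate_visit",
    "error_findings",
    "missing_lines",
]

N_ORGAN_ITEMS = 14

#: Short labels for the graded organ/feature items, keyed by line number 1-14.
ORGAN_LABELS: dict[int, str] = {
    1: "autoimmune cytopenia",
    2: "hemophagocytosis / HLH",
    3: "enteropathy / IBD",
    4: "lymphoproliferation / organomegaly",
    5: "parenchymal lung disease (LIP/GLILD)",
    6: "skin or eye manifestations",
    7: "granulomatous disease (non-GLILD)",
    8: "endocrinopathy",
    9: "arthritis / musculoskeletal",
    10: "AI-hepatitis / cholangitis / pancreatitis",
    11: "glomerulonephritis / nephropathy",
    12: "neurologic immune dysregulation",
    13: "failure to thrive",
    14: "severe / opportunistic infections",
}

#: Labels for every numbered item, including the non-graded lines 15-22.
LINE_LABELS: dict[int, str] = {
    **ORGAN_LABELS,
    15: "Karnofsky/Lansky performance scale (%)",
    16: "hospitalization days per 100 (non-ICU)",
    17: "ICU / mechanical ventilation days per 100",
    18: "immunoglobulin substitution / hypogammaglobulinemia",
    19: "chronic or recurring infestation/infection",
    20: "other organ dysfunction / malady",
    21: "nutrition / dietary status",
    22: "malignancy (noted, not scored)",
}


class IggSubstitution(enum.Enum):
    """Immunoglobulin substitution status (line 18).

    The numeric contribution to the score is 0 for ``NONE``, 2 for
    ``SPORADIC`` and 3 for regular intravenous or subcutaneous substitution
    (the route does not change the points).
    """

    NONE = "none"
    SPORADIC = "sporadic"
    REGULAR_IV = "iv"
    REGULAR_SC = "sc"


_IGG_POINTS = {
    IggSubstitution.NONE: 0,
    IggSubstitution.SPORADIC: 2,
    IggSubstitution.REGULAR_IV: 3,
    IggSubstitution.REGULAR_SC: 3,
}


class InvalidCodeError(ValueError):
    """Raised when a value is not a member of an expected enumeration."""


def igg_numeric(code: IggSubstitution) -> int:
    """Return the score points for an immunoglobulin-substitution status.

    Parameters
    ----------
    code
        A member of :class:`IggSubstitution`. String tokens
        (``"none"``, ``"sporadic"``, ``"iv"``, ``"sc"``) are accepted.

    Returns
    -------
    int
        0 (none), 2 (sporadic) or 3 (regular IV or SC).
    """
    if isinstance(code, str):
        try:
            code = IggSubstitution(code)
        except ValueError as exc:
            raise InvalidCodeError(
                f"unknown immunoglobulin substitution code {code!r}; "
                f"expected one of {[m.value for m in IggSubstitution]}"
            ) from exc
    if not isinstance(code, IggSubstitution):
        raise InvalidCodeError(
            f"unknown immunoglobulin substitution code {code!r}"
        )
    return _IGG_POINTS[code]


@dataclass(frozen=True)
class Finding:
    """One validation finding, attributable to a numbered item line."""

    line: int
    field: str
    message: str
    severity: str = "error"  # "error" or "warning"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] line {self.line} ({self.field}): {self.message}"


@dataclass(frozen=True)
class VisitRecord:
    """A single patient visit with all 22 IDDA2.1 items.

    ``organ_grades`` holds the fourteen graded items (lines 1-14) in fixed
    order; entries may be ``None`` to mark an item as not assessed, which is
    distinct from grade 0 (assessed and absent). The same applies to
    ``chronic_infestation``, ``other_organ_dysfunction`` and
    ``nutrition_status`` (lines 19-21).
    """

    patient_id: str
    visit_date: datetime.date
    organ_grades: tuple[Optional[int], ...]
    performance_scale: int
    hospital_days_per_100: float
    icu_days_per_100: float
    igg_substitution: IggSubstitution
    chronic_infestation: Optional[int]
    other_organ_dysfunction: Optional[int]
    nutrition_status: Optional[int]
    malignancy: bool = False
    malignancy_note: Optional[str] = None
    therapy_phase: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "organ_grades", tuple(self.organ_grades))
        if isinstance(self.igg_substitution, str):
            object.__setattr__(
                self, "igg_substitution", IggSubstitution(self.igg_substitution)
            )
        if isinstance(self.visit_date, str):
            object.__setattr__(
                self, "visit_date", datetime.date.fromisoformat(self.visit_date)
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        """Plain-dict form with ISO date and the line-18 token; lossless."""
        return {
            "patient_id": self.patient_id,
            "visit_date": self.visit_date.isoformat(),
            "therapy_phase": self.therapy_phase,
            "organ_grades": list(self.organ_grades),
            "performance_scale": self.performance_scale,
            "hospital_days_per_100": self.hospital_days_per_100,
            "icu_days_per_100": self.icu_days_per_100,
            "igg_substitution": self.igg_substitution.value,
            "chronic_infestation": self.chronic_infestation,
            "other_organ_dysfunction": self.other_organ_dysfunction,
            "nutrition_status": self.nutrition_status,
            "malignancy": self.malignancy,
            "malignancy_note": self.malignancy_note,
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "VisitRecord":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown VisitRecord keys: {sorted(unknown)}")
        return cls(**data)

    def line_value(self, line: int) -> Optional[float]:
        """Numeric value of a single item line (1-22); ``None`` if missing.

        Line 18 is returned on its points scale (0/2/3); line 22 as 0/1.
        """
        if 1 <= line <= N_ORGAN_ITEMS:
            g = self.organ_grades[line - 1]
            return None if g is None else float(g)
        if line == 15:
            return float(self.performance_scale)
        if line == 16:
            return float(self.hospital_days_per_100)
        if line == 17:
            return float(self.icu_days_per_100)
        if line == 18:
            return float(igg_numeric(self.igg_substitution))
        if line == 19:
            v = self.chronic_infestation
        elif line == 20:
            v = self.other_organ_dysfunction
        elif line == 21:
            v = self.nutrition_status
        elif line == 22:
            return float(self.malignancy)
        else:
            raise ValueError(f"no such item line: {line}")
        return None if v is None else float(v)


_SUPPORTIVE_FIELDS = (
    (19, "chronic_infestation"),
    (20, "other_organ_dysfunction"),
    (21, "nutrition_status"),
)


def validate_visit(record: VisitRecord) -> list[Finding]:
    """Check a visit record against the grading rubrics.

    Returns one :class:`Finding` per violated rule (empty for a conforming
    record). Missing values (``None``) on lines 1-14 and 19-21 are
    permitted and produce no finding; whether they block scoring is decided
    by the scoring missing-value policy, not here.

    A non-decile performance-scale value is reported as a ``warning``
    finding (Karnofsky/Lansky grades are conventionally steps of 10, but
    the score formula divides by the raw value, so intermediate values are
    admissible).
    """
    findings: list[Finding] = []

    grades = record.organ_grades
    if len(grades) != N_ORGAN_ITEMS:
        findings.append(
            Finding(
                line=1,
                field="organ_grades",
                message=f"expected {N_ORGAN_ITEMS} organ grades (lines 1-14), "
                f"got {len(grades)}",
            )
        )
    else:
        for i, g in enumerate(grades, start=1):
            if g is None:
                continue
            if not isinstance(g, (int,)) or isinstance(g, bool) or not 0 <= g <= 4:
                findings.append(
                    Finding(
                        line=i,
                        field="organ_grades",
                        message=f"grade {g!r} on line {i} "
                        f"({ORGAN_LABELS[i]}) outside admissible range 0-4",
                    )
                )

    kps = record.performance_scale
    if not isinstance(kps, int) or isinstance(kps, bool) or not 10 <= kps <= 100:
        findings.append(
            Finding(
                line=15,
                field="performance_scale",
                message=f"performance scale {kps!r} outside admissible "
                "range 10-100 (line 15)",
            )
        )
    elif kps % 10 != 0:
        findings.append(
            Finding(
                line=15,
                field="performance_scale",
                message=f"performance scale {kps} is not a multiple of 10; "
                "accepted, but Karnofsky/Lansky grades are decile-stepped",
                severity="warning",
            )
        )

    hosp = record.hospital_days_per_100
    icu = record.icu_days_per_100
    if not 0 <= hosp <= 100:
        findings.append(
            Finding(
                line=16,
                field="hospital_days_per_100",
                message=f"hospitalization days {hosp!r} outside [0, 100] (line 16)",
            )
        )
    if not 0 <= icu <= 100:
        findings.append(
            Finding(
                line=17,
                field="icu_days_per_100",
                message=f"ICU days {icu!r} outside [0, 100] (line 17)",
            )
        )
    if 0 <= hosp <= 100 and 0 <= icu <= 100 and hosp + icu > 100:
        findings.append(
            Finding(
                line=16,
                field="hospital_days_per_100",
                message=f"hospital ({hosp}) + ICU ({icu}) days exceed the "
                "100-day observation window (lines 16-17)",
            )
        )

    try:
        igg_numeric(record.igg_substitution)
    except InvalidCodeError:
        findings.append(
            Finding(
                line=18,
                field="igg_substitution",
                message=f"unknown immunoglobulin substitution code "
                f"{record.igg_substitution!r} (line 18)",
            )
        )

    for line, name in _SUPPORTIVE_FIELDS:
        v = getattr(record, name)
        if v is None:
            continue
        if not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 4:
            findings.append(
                Finding(
                    line=line,
                    field=name,
                    message=f"value {v!r} on line {line} "
                    f"({LINE_LABELS[line]}) outside admissible range 0-4",
                )
            )

    return findings


def error_findings(record: VisitRecord) -> list[Finding]:
    """Validation findings of severity ``error`` only."""
    return [f for f in validate_visit(record) if f.severity == "error"]


def missing_lines(record: VisitRecord) -> list[int]:
    """Item lines marked missing (``None``): subset of 1-14 and 19-21."""
    out = [i for i, g in enumerate(record.organ_grades, start=1) if g is None]
    out.extend(line for line, name in _SUPPORTIVE_FIELDS if getattr(record, name) is None)
    return out
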