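"""Cohort "kaleidoscope" profiles: 17-feature presence frequencies and radar charts.

The kaleidoscope view reduces the graded IDDA2.1 items to qualitative
presence/absence and plots, for a patient cohort, the percentage of
patients in whom each feature is present on 17 radial axes in a fixed
order: the fourteen organ/feature items (lines 1-14), then other organ
dysfunction (line 20), then hypogammaglobulinemia / immunoglobulin
substitution (line 18), then malignancy (line 22). The performance scale,
hospitalization/ICU days and asymptomatic chronic infestation (lines
15-17, 19) and nutrition status (line 21) do not appear on the radar.

Presence means: grade >= 1 for graded items, any substitution (points > 0)
for line 18, and a set flag for line 22. Items not assessed in a patient
are excluded from that axis's denominator rather than counted as absent,
so per-axis denominators can differ within one cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .data_model import (
    LINE_LABELS,
    N_ORGAN_ITEMS,
    VisitRecord,
    igg_numeric,
)

__all__ = [
    "N_AXES",
    "AXIS_LINES",
    "AXIS_LABELS",
    "EmptyCohortError",
    "CohortProfile",
    "presence_vector",
    "cohort_frequencies",
    "select_representative",
    "render_kaleidoscope",
    "profile_table",
]

N_AXES = 17

#: Item line shown on each radar axis, in fixed circular order.
AXIS_LINES: tuple[int, ...] = tuple(range(1, N_ORGAN_ITEMS + 1)) + (20, 18, 22)

#: Axis captions, same order as :data:`AXIS_LINES`.
AXIS_LABELS: tuple[str, ...] = tuple(LINE_LABELS[line] for line in AXIS_LINES[:-2]) + (
    "hypogammaglobulinemia / IgG substitution",
    "malignancy, lymphoma",
)


class EmptyCohortError(ValueError):
    """A cohort aggregation was requested over zero patients."""


def presence_vector(record: VisitRecord) -> tuple[Optional[bool], ...]:
    """Qualitative presence of the 17 kaleidoscope features for one patient.

    Returns a 17-tuple in :data:`AXIS_LINES` order; entries are ``True``
    (present), ``False`` (assessed and absent), or ``None`` (not assessed).
    """
    out: list[Optional[bool]] = []
    for line in AXIS_LINES:
        if line == 18:
            out.append(igg_numeric(record.igg_substitution) > 0)
        elif line == 22:
            out.append(bool(record.malignancy))
        else:
            v = record.line_value(line)
            out.append(None if v is None else v >= 1)
    return tuple(out)


@dataclass(frozen=True)
class CohortProfile:
    """Per-cohort presence frequencies on the 17 kaleidoscope axes.

    ``frequencies`` are percentages in [0, 100], or ``None`` where no
    patient had the feature assessed (denominator 0); ``denominators``
    count patients with non-missing data per axis, never exceeding
    ``n_patients``.
    """

    label: str
    n_patients: int
    frequencies: tuple[Optional[float], ...]
    denominators: tuple[int, ...]
    presence_counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.frequencies) == len(self.denominators)
            == len(self.presence_counts) == N_AXES
        ):
            raise ValueError(f"profile must have exactly {N_AXES} axes")


def cohort_frequencies(
    records: Sequence[VisitRecord], label: str
) -> CohortProfile:
    """Aggregate one representative record per patient into a cohort profile.

    The caller chooses which visit represents each patient (see
    :func:`select_representative`); pass exactly one record per patient.
    Frequencies are 100 x presence count / per-axis denominator, where the
    denominator counts patients with the feature assessed.
    """
    records = list(records)
    if not records:
        raise EmptyCohortError(f"cohort {label!r} has no patients")
    counts = [0] * N_AXES
    denoms = [0] * N_AXES
    for rec in records:
        for i, present in enumerate(presence_vector(rec)):
            if present is None:
                continue
            denoms[i] += 1
            counts[i] += int(present)
    freqs = tuple(
        (100.0 * c / d) if d else None for c, d in zip(counts, denoms)
    )
    return CohortProfile(
        label=label,
        n_patients=len(records),
        frequencies=freqs,
        denominators=tuple(denoms),
        presence_counts=tuple(counts),
    )


def select_representative(
    visits: Sequence[VisitRecord], policy: str = "latest"
) -> VisitRecord:
    """Pick or build the record representing one patient's phenotype.

    ``latest`` returns the most recent visit. ``worst`` builds a
    lifetime-phenotype record taking, per item, the worst (highest) grade
    ever observed, the strongest substitution status, the lowest
    performance value and the highest day counts — matching cohort
    summaries assembled from case series, which report whether a feature
    was ever present. Missing entries stay missing only if missing at
    every visit.
    """
    visits = list(visits)
    if not visits:
        raise EmptyCohortError("no visits for patient")
    if len({v.patient_id for v in visits}) > 1:
        raise ValueError("visits mix patient ids")
    if policy == "latest":
        return max(visits, key=lambda v: v.visit_date)
    if policy != "worst":
        raise ValueError(f"unknown visit policy {policy!r}; use 'latest' or 'worst'")

    def worst(values):
        seen = [v for v in values if v is not None]
        return max(seen) if seen else None

    latest = max(visits, key=lambda v: v.visit_date)
    grades = tuple(
        worst(v.organ_grades[i] for v in visits) for i in range(N_ORGAN_ITEMS)
    )
    igg = max(visits, key=lambda v: igg_numeric(v.igg_substitution)).igg_substitution
    return VisitRecord(
        patient_id=latest.patient_id,
        visit_date=latest.visit_date,
        therapy_phase=None,
        organ_grades=grades,
        performance_scale=min(v.performance_scale for v in visits),
        hospital_days_per_100=max(v.hospital_days_per_100 for v in visits),
        icu_days_per_100=max(v.icu_days_per_100 for v in visits),
        igg_substitution=igg,
        chronic_infestation=worst(v.chronic_infestation for v in visits),
        other_organ_dysfunction=worst(v.other_organ_dysfunction for v in visits),
        nutrition_status=worst(v.nutrition_status for v in visits),
        malignancy=any(v.malignancy for v in visits),
    )


def profile_table(profiles: Sequence[CohortProfile]) -> str:
    """Render profiles as a deterministic TSV string.

    Columns: cohort, n_patients, axis_index (1-17), axis_line (item line
    number), axis_label, presence_count, denominator, frequency_pct.
    Unavailable axes (denominator 0) carry an empty frequency cell. The
    output is byte-stable for identical input.
    """
    lines = [
        "cohort\tn_patients\taxis_index\taxis_line\taxis_label\t"
        "presence_count\tdenominator\tfrequency_pct"
    ]
    for prof in profiles:
        for i in range(N_AXES):
            freq = prof.frequencies[i]
            freq_s = "" if freq is None else f"{freq:.4f}"
            lines.append(
                f"{prof.label}\t{prof.n_patients}\t{i + 1}\t{AXIS_LINES[i]}\t"
                f"{AXIS_LABELS[i]}\t{prof.presence_counts[i]}\t"
                f"{prof.denominators[i]}\t{freq_s}"
            )
    return "\n".join(lines) + "\n"


def render_kaleidoscope(
    profiles: CohortProfile | Sequence[CohortProfile],
    out_path,
    table_path=None,
):
    """Draw the radar (spider) chart of one or more cohort profiles.

    17 axes in the fixed order, radial scale 0-100%. A single profile is
    titled ``"<label> (n=<n>)"``; several profiles are overlaid with a
    legend. Axes with denominator 0 are drawn as gaps in the polygon
    rather than as zeros. If ``table_path`` is given, the underlying
    frequency table is written there as TSV (byte-stable).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(profiles, CohortProfile):
        profiles = [profiles]
    profiles = list(profiles)
    if not profiles:
        raise EmptyCohortError("no profiles to render")

    angles = np.linspace(0, 2 * np.pi, N_AXES, endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7.5, 7.5))
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    for prof in profiles:
        vals = np.array(
            [math.nan if f is None else f for f in prof.frequencies], dtype=float
        )
        closed_angles = np.append(angles, angles[0])
        closed_vals = np.append(vals, vals[0])
        ax.plot(
            closed_angles,
            closed_vals,
            linewidth=1.5,
            label=f"{prof.label} (n={prof.n_patients})",
        )
        ax.fill(closed_angles, np.nan_to_num(closed_vals), alpha=0.12)
    ax.set_xticks(angles)
    ax.set_xticklabels(
        [f"{i + 1}. {lab}" for i, lab in enumerate(AXIS_LABELS)], fontsize=6
    )
    ax.set_ylim(0, 100)
    ax.set_yticks([0, 25, 50, 75, 100])
    ax.set_yticklabels(["0", "25", "50", "75", "100%"], fontsize=7)
    if len(profiles) == 1:
        ax.set_title(f"{profiles[0].label} (n={profiles[0].n_patients})")
    else:
        ax.legend(loc="upper right", bbox_to_anchor=(1.35, 1.1), fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)

    if table_path is not None:
        with open(table_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(profile_table(profiles))
    return out_path
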