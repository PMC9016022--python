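"""Readers and writers for the visit CSV and frequency-table TSV dialects.

Visit CSV: one row per visit, UTF-8, comma-separated, header required.
Columns: ``patient_id, visit_date, therapy_phase, p01..p14,
p15_performance, p16_hosp, p17_icu, p18_igg, p19, p20, p21,
p22_malignancy, p22_note``. ``p18_igg`` takes a token from
``{none, sporadic, iv, sc}``; an empty cell means *missing* (allowed on
p01-p14 and p19-p21), which is distinct from 0.

Frequency TSV: long format, one row per (cohort, axis) with columns
``cohort, n_patients, axis_index, axis_line, axis_label, presence_count,
denominator, frequency_pct``; an empty frequency cell marks an axis with
denominator 0. Reading pivots this into a :class:`~idda.clustering.PhenotypeMatrix`.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .clustering import DEFAULT_EPS, PhenotypeMatrix
from .data_model import (
    N_ORGAN_ITEMS,
    IggSubstitution,
    VisitRecord,
)
from .kaleidoscope import AXIS_LABELS, N_AXES, CohortProfile, profile_table
from .synthetic import ArchetypeSpec

__all__ = [
    "ParseError",
    "VISIT_COLUMNS",
    "read_visits",
    "write_visits",
    "write_frequency_table",
    "read_frequency_table",
    "read_archetypes",
    "write_archetypes",
    "RunConfig",
]


class ParseError(ValueError):
    """Malformed input file; carries the 1-based row number where known."""

    def __init__(self, message: str, row: Optional[int] = None):
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)


VISIT_COLUMNS: tuple[str, ...] = (
    ("patient_id", "visit_date", "therapy_phase")
    + tuple(f"p{i:02d}" for i in range(1, N_ORGAN_ITEMS + 1))
    + ("p15_performance", "p16_hosp", "p17_icu", "p18_igg", "p19", "p20", "p21",
       "p22_malignancy", "p22_note")
)

_IGG_TOKENS = {m.value: m for m in IggSubstitution}


def _opt_int(cell: str, column: str, row: int) -> Optional[int]:
    if cell == "":
        return None
    try:
        return int(cell)
    except ValueError as exc:
        raise ParseError(f"column {column}: {cell!r} is not an integer", row) from exc


def _req_number(cell: str, column: str, row: int) -> float:
    if cell == "":
        raise ParseError(f"column {column} may not be empty", row)
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"column {column}: {cell!r} is not a number", row) from exc


def read_visits(path) -> list[VisitRecord]:
    """Read the visit CSV dialect into records (no validation applied).

    Raises :class:`ParseError` with a row number for structural problems;
    grading-rubric violations are left to
    :func:`~idda.data_model.validate_visit` so they surface as findings,
    not exceptions.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ParseError("file is empty (header required)")
        missing_cols = [c for c in VISIT_COLUMNS if c not in reader.fieldnames]
        if missing_cols:
            raise ParseError(f"missing columns: {missing_cols}")
        records: list[VisitRecord] = []
        for rownum, row in enumerate(reader, start=2):
            if row.get("patient_id") in (None, ""):
                raise ParseError("patient_id may not be empty", rownum)
            try:
                igg_token = (row["p18_igg"] or "").strip().lower()
                if igg_token not in _IGG_TOKENS:
                    raise ParseError(
                        f"column p18_igg: unknown token {row['p18_igg']!r}; "
                        f"expected one of {sorted(_IGG_TOKENS)}",
                        rownum,
                    )
                perf_cell = row["p15_performance"]
                if perf_cell == "":
                    raise ParseError("column p15_performance may not be empty", rownum)
                try:
                    perf = int(perf_cell)
                except ValueError as exc:
                    raise ParseError(
                        f"column p15_performance: {perf_cell!r} is not an integer",
                        rownum,
                    ) from exc
                rec = VisitRecord(
                    patient_id=row["patient_id"],
                    visit_date=row["visit_date"],
                    therapy_phase=row["therapy_phase"] or None,
                    organ_grades=tuple(
                        _opt_int(row[f"p{i:02d}"], f"p{i:02d}", rownum)
                        for i in range(1, N_ORGAN_ITEMS + 1)
                    ),
                    performance_scale=perf,
                    hospital_days_per_100=_req_number(row["p16_hosp"], "p16_hosp", rownum),
                    icu_days_per_100=_req_number(row["p17_icu"], "p17_icu", rownum),
                    igg_substitution=_IGG_TOKENS[igg_token],
                    chronic_infestation=_opt_int(row["p19"], "p19", rownum),
                    other_organ_dysfunction=_opt_int(row["p20"], "p20", rownum),
                    nutrition_status=_opt_int(row["p21"], "p21", rownum),
                    malignancy=row["p22_malignancy"].strip() in ("1", "true", "True"),
                    malignancy_note=row["p22_note"] or None,
                )
            except ParseError:
                raise
            except (ValueError, KeyError) as exc:
                raise ParseError(str(exc), rownum) from exc
            records.append(rec)
    return records


def _num_cell(x: float) -> str:
    """Integers without a trailing .0; everything else via repr (lossless)."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_visits(records: Sequence[VisitRecord], path) -> None:
    """Write records in the visit CSV dialect (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(VISIT_COLUMNS)
        for rec in records:
            row = [rec.patient_id, rec.visit_date.isoformat(), rec.therapy_phase or ""]
            row.extend("" if g is None else str(g) for g in rec.organ_grades)
            row.append(str(rec.performance_scale))
            row.append(_num_cell(rec.hospital_days_per_100))
            row.append(_num_cell(rec.icu_days_per_100))
            row.append(rec.igg_substitution.value)
            for v in (rec.chronic_infestation, rec.other_organ_dysfunction,
                      rec.nutrition_status):
                row.append("" if v is None else str(v))
            row.append("1" if rec.malignancy else "0")
            row.append(rec.malignancy_note or "")
            writer.writerow(row)


def write_frequency_table(profiles: Sequence[CohortProfile], path) -> None:
    """Write cohort profiles as the long-format frequency TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(profile_table(list(profiles)))


def read_frequency_table(path, impute: float = DEFAULT_EPS) -> PhenotypeMatrix:
    """Read a frequency TSV into a phenotype matrix of proportions.

    Frequencies are normally percentages (0-100). If every available value
    is <= 1 the table is assumed to hold proportions already and is taken
    as-is, with a warning. Axes with denominator 0 are imputed at the
    truncation floor (see :meth:`PhenotypeMatrix.from_profiles`).
    """
    path = Path(path)
    cohorts: dict[str, dict] = {}
    with path.open(encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        needed = {"cohort", "n_patients", "axis_index", "frequency_pct"}
        if reader.fieldnames is None or not needed <= set(reader.fieldnames):
            raise ParseError(
                f"frequency table must have columns {sorted(needed)}"
            )
        for rownum, row in enumerate(reader, start=2):
            label = row["cohort"]
            entry = cohorts.setdefault(
                label,
                {"n": int(row["n_patients"]), "freq": [None] * N_AXES},
            )
            idx = int(row["axis_index"]) - 1
            if not 0 <= idx < N_AXES:
                raise ParseError(f"axis_index out of range 1-{N_AXES}", rownum)
            cell = row["frequency_pct"]
            if cell != "":
                f = float(cell)
                if not 0 <= f <= 100:
                    raise ParseError(
                        f"frequency {f!r} outside [0, 100]", rownum
                    )
                entry["freq"][idx] = f
    if not cohorts:
        raise ParseError("frequency table has no data rows")

    available = [
        f for entry in cohorts.values() for f in entry["freq"] if f is not None
    ]
    as_proportions = bool(available) and max(available) <= 1.0
    if as_proportions:
        warnings.warn(
            "all frequencies are <= 1; interpreting the table as proportions, "
            "not percentages",
            stacklevel=2,
        )

    labels, rows = [], []
    for label, entry in cohorts.items():
        row_vals = []
        for i, f in enumerate(entry["freq"]):
            if f is None:
                warnings.warn(
                    f"cohort {label!r}: axis {i + 1} unavailable, imputing at {impute}",
                    stacklevel=2,
                )
                row_vals.append(impute)
            else:
                row_vals.append(f if as_proportions else f / 100.0)
        labels.append(f"{label} (n={entry['n']})")
        rows.append(row_vals)
    return PhenotypeMatrix(
        row_labels=tuple(labels),
        col_labels=AXIS_LABELS,
        values=np.array(rows, dtype=float),
    )


def read_archetypes(path) -> list[ArchetypeSpec]:
    """Load archetype specs from a YAML (or JSON) config.

    The file holds either a list of archetype mappings or a mapping with
    an ``archetypes`` key. Unknown keys are rejected.
    """
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = data.get("archetypes", data)
    if not isinstance(data, list):
        raise ParseError("archetype config must be a list of archetype mappings")
    return [ArchetypeSpec.from_dict(d) for d in data]


def write_archetypes(specs: Sequence[ArchetypeSpec], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"archetypes": [s.to_dict() for s in specs]}, fh, sort_keys=False
        )


@dataclass
class RunConfig:
    """Run-wide options shared by the CLI subcommands.

    Loaded from a YAML mapping; unknown keys are rejected so typos do not
    silently fall back to defaults.
    """

    missing_policy: str = "refuse"
    visit_policy: str = "latest"
    eps: float = DEFAULT_EPS
    scale: str = "none"
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
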