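"""Synthetic IEI cohorts with disease-archetype structure.

Real multi-disease activity-score datasets are assembled from published
case series and are not publicly deposited, so the package ships a
generative model that emulates their structure: each disease *archetype*
is a vector of presence probabilities on the 17 kaleidoscope axes plus
distributions for severity grades, supportive-care items, performance
scale and hospitalization burden. Cohorts drawn from an archetype have
empirical feature frequencies that concentrate around the archetype's
probabilities, which is exactly the signal the kaleidoscope and clustering
views are meant to pick up.

The model is deliberately minimal: features are sampled independently per
patient (no correlation structure between organ systems), one visit per
patient, and the performance scale and hospital-day burden are driven by
the number of present features. All randomness flows from a single integer
seed through one ``numpy`` generator per cohort.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import IggSubstitution, VisitRecord, error_findings
from .kaleidoscope import AXIS_LINES, N_AXES, CohortProfile, cohort_frequencies

__all__ = [
    "ArchetypeSpec",
    "Cohort",
    "Study",
    "sample_cohort",
    "sample_study",
    "default_study_archetypes",
]

_BASE_DATE = datetime.date(2021, 1, 1)

# axis indices (0-based) of the non-graded kaleidoscope axes
_AXIS_IGG = AXIS_LINES.index(18)
_AXIS_MALIGNANCY = AXIS_LINES.index(22)
_AXIS_OTHER_ORGAN = AXIS_LINES.index(20)


def _check_dist(name: str, probs: Sequence[float], length: int) -> tuple[float, ...]:
    p = tuple(float(x) for x in probs)
    if len(p) != length:
        raise ValueError(f"{name} must have {length} entries, got {len(p)}")
    if any(x < 0 or x > 1 for x in p):
        raise ValueError(f"{name} entries must be probabilities in [0, 1]")
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {sum(p)!r}")
    return p


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative description of one disease cohort.

    Parameters
    ----------
    name
        Archetype label.
    presence_probs
        17 probabilities, one per kaleidoscope axis in the fixed order
        (lines 1-14, 20, 18, 22). The last two drive immunoglobulin
        substitution and malignancy.
    severity_dist
        Distribution over grades 1-4 given that a graded feature is
        present; default uniform.
    kps_base, kps_drop_per_feature
        Mean Karnofsky/Lansky value for a feature-free patient and the
        downward shift per present feature; the result is rounded to the
        nearest decile and clamped to [10, 100].
    hosp_rate, icu_rate
        Cohort-mean hospitalization and ICU days per 100; each patient's
        mean scales with their feature burden relative to the archetype's
        expected burden, and days are drawn from a normal truncated to the
        100-day window (ICU days truncated to the remainder).
    igg_category_probs
        Distribution over (sporadic, regular IV, regular SC) given that
        the substitution axis fired.
    infestation_probs, nutrition_probs
        Distributions over grades 0-4 for lines 19 and 21, which are not
        kaleidoscope axes but do enter the numeric score.
    """

    name: str
    presence_probs: tuple[float, ...]
    severity_dist: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    kps_base: float = 90.0
    kps_drop_per_feature: float = 4.0
    hosp_rate: float = 8.0
    icu_rate: float = 1.0
    igg_category_probs: tuple[float, ...] = (0.2, 0.4, 0.4)
    infestation_probs: tuple[float, ...] = (0.70, 0.12, 0.10, 0.05, 0.03)
    nutrition_probs: tuple[float, ...] = (0.80, 0.10, 0.05, 0.03, 0.02)

    def __post_init__(self) -> None:
        probs = tuple(float(x) for x in self.presence_probs)
        if len(probs) != N_AXES:
            raise ValueError(
                f"presence_probs must have {N_AXES} entries, got {len(probs)}"
            )
        if any(x < 0 or x > 1 for x in probs):
            raise ValueError("presence_probs must lie in [0, 1]")
        object.__setattr__(self, "presence_probs", probs)
        object.__setattr__(
            self, "severity_dist", _check_dist("severity_dist", self.severity_dist, 4)
        )
        object.__setattr__(
            self,
            "igg_category_probs",
            _check_dist("igg_category_probs", self.igg_category_probs, 3),
        )
        object.__setattr__(
            self,
            "infestation_probs",
            _check_dist("infestation_probs", self.infestation_probs, 5),
        )
        object.__setattr__(
            self,
            "nutrition_probs",
            _check_dist("nutrition_probs", self.nutrition_probs, 5),
        )
        if not 10 <= self.kps_base <= 100:
            raise ValueError("kps_base must lie in [10, 100]")
        if self.hosp_rate < 0 or self.icu_rate < 0:
            raise ValueError("hosp_rate and icu_rate must be non-negative")

    @property
    def igg_prob(self) -> float:
        """Probability of any immunoglobulin substitution (axis 16)."""
        return self.presence_probs[_AXIS_IGG]

    @property
    def malignancy_prob(self) -> float:
        """Probability of a noted malignancy (axis 17)."""
        return self.presence_probs[_AXIS_MALIGNANCY]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "presence_probs": list(self.presence_probs),
            "severity_dist": list(self.severity_dist),
            "kps_base": self.kps_base,
            "kps_drop_per_feature": self.kps_drop_per_feature,
            "hosp_rate": self.hosp_rate,
            "icu_rate": self.icu_rate,
            "igg_category_probs": list(self.igg_category_probs),
            "infestation_probs": list(self.infestation_probs),
            "nutrition_probs": list(self.nutrition_probs),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArchetypeSpec":
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ArchetypeSpec keys: {sorted(unknown)}")
        return cls(**data)


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lo: float, hi: float) -> float:
    """Draw from N(mu, sd) truncated to [lo, hi] by rejection (fallback: clip)."""
    if hi <= lo:
        return lo
    if sd <= 0:
        return float(min(max(mu, lo), hi))
    for _ in range(200):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mu, lo), hi))


def sample_cohort(
    spec: ArchetypeSpec,
    n: int,
    seed: int,
    label: Optional[str] = None,
    visit_date: datetime.date = _BASE_DATE,
) -> list[VisitRecord]:
    """Draw ``n`` patients (one visit each) from an archetype.

    Deterministic given ``(spec, n, seed)``. Every returned record passes
    validation with zero findings.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    label = label or spec.name
    probs = np.asarray(spec.presence_probs)
    expected_burden = max(float(probs.sum()), 1e-9)
    grades_support = np.arange(1, 5)
    records: list[VisitRecord] = []
    for i in range(n):
        present = rng.random(N_AXES) < probs
        burden = int(present.sum())

        def grade(on: bool) -> int:
            if not on:
                return 0
            return int(rng.choice(grades_support, p=spec.severity_dist))

        organ = tuple(grade(present[j]) for j in range(14))
        other_organ = grade(present[_AXIS_OTHER_ORGAN])
        if present[_AXIS_IGG]:
            igg = [
                IggSubstitution.SPORADIC,
                IggSubstitution.REGULAR_IV,
                IggSubstitution.REGULAR_SC,
            ][int(rng.choice(3, p=spec.igg_category_probs))]
        else:
            igg = IggSubstitution.NONE

        kps = spec.kps_base - spec.kps_drop_per_feature * burden
        kps = int(min(100, max(10, round(kps / 10.0) * 10)))

        rel_burden = burden / expected_burden
        hosp = round(
            _truncated_normal(
                rng, spec.hosp_rate * rel_burden, max(spec.hosp_rate, 1.0) / 2,
                0.0, 100.0,
            ),
            1,
        )
        icu = round(
            _truncated_normal(
                rng, spec.icu_rate * rel_burden, max(spec.icu_rate, 1.0) / 2,
                0.0, 100.0 - hosp,
            ),
            1,
        )
        icu = min(icu, 100.0 - hosp)  # rounding must not breach the 100-day window

        rec = VisitRecord(
            patient_id=f"{label}-P{i + 1:04d}",
            visit_date=visit_date,
            therapy_phase=None,
            organ_grades=organ,
            performance_scale=kps,
            hospital_days_per_100=hosp,
            icu_days_per_100=icu,
            igg_substitution=igg,
            chronic_infestation=int(rng.choice(5, p=spec.infestation_probs)),
            other_organ_dysfunction=other_organ,
            nutrition_status=int(rng.choice(5, p=spec.nutrition_probs)),
            malignancy=bool(present[_AXIS_MALIGNANCY]),
        )
        records.append(rec)
    return records


@dataclass(frozen=True)
class Cohort:
    """One simulated cohort with its ground-truth archetype."""

    label: str
    archetype: str
    records: tuple[VisitRecord, ...]

    def profile(self) -> CohortProfile:
        return cohort_frequencies(list(self.records), self.label)


@dataclass(frozen=True)
class Study:
    """A multi-cohort synthetic study with ground-truth assignments."""

    cohorts: tuple[Cohort, ...]

    @property
    def truth(self) -> dict[str, str]:
        """Cohort label -> archetype name."""
        return {c.label: c.archetype for c in self.cohorts}

    def profiles(self) -> list[CohortProfile]:
        return [c.profile() for c in self.cohorts]


def sample_study(
    archetypes: Sequence[ArchetypeSpec],
    cohorts_per_archetype: int,
    n_per_cohort: int,
    seed: int,
) -> Study:
    """Draw several cohorts per archetype with per-cohort labels and truth.

    Cohort labels are ``"<archetype>-C<k>"``. Per-cohort seeds are spawned
    from the single study seed, so the study is reproducible as a whole
    and cohorts are statistically independent.
    """
    archetypes = list(archetypes)
    if len(archetypes) < 2:
        raise ValueError("a study needs at least 2 archetypes")
    if cohorts_per_archetype < 1 or n_per_cohort < 1:
        raise ValueError("cohorts_per_archetype and n_per_cohort must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(archetypes) * cohorts_per_archetype)
    cohorts: list[Cohort] = []
    idx = 0
    for spec in archetypes:
        for k in range(cohorts_per_archetype):
            label = f"{spec.name}-C{k + 1}"
            child_seed = int(children[idx].generate_state(1)[0]) % (2**31)
            recs = sample_cohort(spec, n_per_cohort, seed=child_seed, label=label)
            cohorts.append(Cohort(label=label, archetype=spec.name, records=tuple(recs)))
            idx += 1
    return Study(cohorts=tuple(cohorts))


def default_study_archetypes() -> list[ArchetypeSpec]:
    """Three illustrative, well-separated disease archetypes.

    Loosely styled on (i) a regulatory T-cell disorder with broad
    autoimmunity, (ii) an antibody-deficiency phenotype dominated by
    infections, lung disease and immunoglobulin substitution, and (iii) an
    EBV-susceptibility phenotype with hemophagocytosis, lymphoproliferation
    and lymphoma risk. Each pair of archetypes differs by at least 0.4 in
    presence probability on at least six of the 17 axes, which makes the
    cohorts cleanly separable by the clustering pipeline at realistic
    cohort sizes. Probabilities are illustrative, not calibrated to any
    published cohort.
    """
    treg = ArchetypeSpec(
        name="tregopathy",
        presence_probs=(
            0.90, 0.30, 0.85, 0.70, 0.40, 0.70, 0.20, 0.75, 0.30, 0.35,
            0.30, 0.25, 0.60, 0.50, 0.30, 0.50, 0.10,
        ),
        hosp_rate=12.0,
        icu_rate=1.5,
    )
    cvid_like = ArchetypeSpec(
        name="cvid-like",
        presence_probs=(
            0.25, 0.05, 0.30, 0.50, 0.65, 0.25, 0.45, 0.10, 0.20, 0.15,
            0.10, 0.10, 0.15, 0.85, 0.25, 0.95, 0.15,
        ),
        hosp_rate=6.0,
        icu_rate=0.5,
    )
    ebv_pird = ArchetypeSpec(
        name="ebv-pird",
        presence_probs=(
            0.35, 0.80, 0.15, 0.90, 0.15, 0.10, 0.05, 0.05, 0.05, 0.30,
            0.05, 0.30, 0.30, 0.70, 0.20, 0.35, 0.55,
        ),
        hosp_rate=15.0,
        icu_rate=3.0,
    )
    return [treg, cvid_like, ebv_pird]
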