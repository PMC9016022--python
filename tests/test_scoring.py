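import datetime
import itertools

import pytest
from hypothesis import given, strategies as st

from idda.scoring import (
    MAX_TOTAL,
    InvalidRecordError,
    MissingDataError,
    MissingPolicy,
    TrajectoryError,
    compute_score,
    hosp_term,
    icu_term,
    performance_multiplier,
    phase_delta,
    score_trajectory,
    trajectory_summary,
)

from conftest import make_record, valid_records
from oracles import record_excel_total


class TestFormulaTerms:
    @pytest.mark.parametrize(
        "days,expected", [(0, 0.0), (20, 2.0), (39.9, 3.99), (40, 4.0), (60, 4.0), (100, 4.0)]
    )
    def test_hospitalization_capped_at_forty_days(self, days, expected):
        assert hosp_term(days) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "days,expected", [(0, 0.0), (5, 4.0), (9.9, 7.92), (10, 8.0), (25, 8.0), (100, 8.0)]
    )
    def test_icu_capped_at_ten_days(self, days, expected):
        assert icu_term(days) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kps,expected", [(100, 1.5), (70, 150 / 70), (30, 5.0), (29, 6.0), (20, 6.0), (10, 6.0)]
    )
    def test_performance_multiplier(self, kps, expected):
        assert performance_multiplier(kps) == pytest.approx(expected)

    def test_terms_reject_out_of_range(self):
        with pytest.raises(ValueError, match="line 16"):
            hosp_term(101)
        with pytest.raises(ValueError, match="line 17"):
            icu_term(-1)
        with pytest.raises(ValueError, match="line 15"):
            performance_multiplier(5)

    def test_boundary_continuity_and_multiplier_jump(self):
        # both hospitalization branches agree at 40 days, both ICU branches at 10
        assert hosp_term(40) == 40 * 0.1
        assert icu_term(10) == 10 * 0.8
        # the multiplier floor creates a genuine jump of 1.0 between 30% and 29%
        assert performance_multiplier(29) - performance_multiplier(30) == pytest.approx(1.0)


class TestComputeScore:
    def test_zero_record_scores_zero(self, zero_record):
        b = compute_score(zero_record)
        assert (b.organ_sum, b.hosp_term, b.icu_term, b.supportive_sum) == (0, 0, 0, 0)
        assert b.multiplier == 1.5
        assert b.total == 0.0

    def test_worked_example(self):
        # organ grades summing 13, 20 hospital days, regular IVIG,
        # infestation 2, other organ 1, nutrition 2, Karnofsky 70%
        rec = make_record(
            organ_grades=(4, 3, 2, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0),
            hospital_days_per_100=20.0,
            igg_substitution="iv",
            chronic_infestation=2,
            other_organ_dysfunction=1,
            nutrition_status=2,
            performance_scale=70,
        )
        b = compute_score(rec)
        assert b.organ_sum == 13
        assert b.hosp_term == 2.0
        assert b.supportive_sum == 8
        assert b.total == pytest.approx((13 + 2 + 0 + 8) * 150 / 70)

    def test_maximum_record_attains_498(self):
        rec = make_record(
            organ_grades=(4,) * 14,
            hospital_days_per_100=50.0,
            icu_days_per_100=12.0,
            igg_substitution="sc",
            chronic_infestation=4,
            other_organ_dysfunction=4,
            nutrition_status=4,
            performance_scale=20,
        )
        assert compute_score(rec).total == pytest.approx(MAX_TOTAL)

    def test_no_extreme_record_exceeds_the_maximum(self):
        # brute force over a grid of extreme values of every term
        for grades, hosp, icu, igg, supp, kps in itertools.product(
            [(0,) * 14, (4,) * 14],
            [0.0, 39.9, 40.0],
            [0.0, 9.9, 10.0],
            ["none", "sporadic", "iv"],
            [0, 4],
            [10, 29, 30, 100],
        ):
            if hosp + icu > 100:
                continue
            rec = make_record(
                organ_grades=grades,
                hospital_days_per_100=hosp,
                icu_days_per_100=icu,
                igg_substitution=igg,
                chronic_infestation=supp,
                other_organ_dysfunction=supp,
                nutrition_status=supp,
                performance_scale=kps,
            )
            assert compute_score(rec).total <= MAX_TOTAL + 1e-12

    def test_malignancy_noted_but_never_scored(self, zero_record):
        rec = make_record(malignancy=True, malignancy_note="DLBCL")
        b = compute_score(rec)
        assert b.total == 0.0
        assert b.malignancy_flag is True

    def test_missing_policy_refuse_and_zero(self):
        rec = make_record(organ_grades=(None, 3) + (0,) * 12)
        with pytest.raises(MissingDataError) as exc:
            compute_score(rec)
        assert exc.value.lines == [1]
        b = compute_score(rec, MissingPolicy.ZERO)
        assert b.organ_sum == 3

    def test_invalid_record_refused(self):
        rec = make_record(performance_scale=105)
        with pytest.raises(InvalidRecordError):
            compute_score(rec)

    @given(valid_records())
    def test_agrees_with_spreadsheet_transcription(self, rec):
        b = compute_score(rec)
        assert b.total == pytest.approx(record_excel_total(rec), rel=1e-9)
        assert b.total == pytest.approx(
            (b.organ_sum + b.hosp_term + b.icu_term + b.supportive_sum) * b.multiplier,
            rel=1e-9,
        )

    @given(valid_records())
    def test_total_in_range_and_zero_iff_all_items_zero(self, rec):
        b = compute_score(rec)
        assert 0 <= b.total <= MAX_TOTAL + 1e-9
        contributing_zero = (
            b.organ_sum == 0
            and rec.hospital_days_per_100 == 0
            and rec.icu_days_per_100 == 0
            and b.supportive_sum == 0
        )
        assert (b.total == 0) == contributing_zero


class TestMonotonicity:
    @given(valid_records(), st.integers(0, 13))
    def test_raising_an_organ_grade_never_lowers_the_total(self, rec, idx):
        if rec.organ_grades[idx] == 4:
            return
        grades = list(rec.organ_grades)
        grades[idx] += 1
        bumped = make_record(**{**rec.to_dict(), "organ_grades": tuple(grades)})
        assert compute_score(bumped).total >= compute_score(rec).total - 1e-12

    @given(valid_records())
    def test_more_hospital_or_icu_days_never_lower_the_total(self, rec):
        base = compute_score(rec).total
        room = 100 - rec.hospital_days_per_100 - rec.icu_days_per_100
        bump = min(5.0, room)
        more_hosp = make_record(
            **{**rec.to_dict(),
               "hospital_days_per_100": rec.hospital_days_per_100 + bump}
        )
        more_icu = make_record(
            **{**rec.to_dict(), "icu_days_per_100": rec.icu_days_per_100 + bump}
        )
        assert compute_score(more_hosp).total >= base - 1e-12
        assert compute_score(more_icu).total >= base - 1e-12

    @given(valid_records())
    def test_better_performance_never_raises_the_total(self, rec):
        if rec.performance_scale == 100:
            return
        better = make_record(
            **{**rec.to_dict(), "performance_scale": rec.performance_scale + 10}
        )
        assert compute_score(better).total <= compute_score(rec).total + 1e-12


def _visit(day, total_grade, phase=None, pid="P001"):
    grades = [0] * 14
    grades[0] = total_grade
    return make_record(
        patient_id=pid,
        visit_date=datetime.date(2021, 1, day),
        organ_grades=tuple(grades),
        therapy_phase=phase,
    )


class TestTrajectory:
    def test_sorted_by_date_and_permutation_stable(self):
        visits = [_visit(20, 2), _visit(5, 4), _visit(12, 3)]
        points = score_trajectory(visits)
        assert [p.visit_date.day for p in points] == [5, 12, 20]
        assert points == score_trajectory(list(reversed(visits)))

    def test_single_visit_and_summaries(self):
        assert trajectory_summary(score_trajectory([_visit(1, 2)])) == "stable"
        falling = score_trajectory([_visit(1, 4), _visit(10, 2), _visit(20, 0)])
        assert [p.breakdown.total for p in falling] == [6.0, 3.0, 0.0]
        assert trajectory_summary(falling) == "improving"
        rising = score_trajectory([_visit(1, 0), _visit(10, 3)])
        assert trajectory_summary(rising) == "worsening"
        mixed = score_trajectory([_visit(1, 0), _visit(10, 3), _visit(20, 1)])
        assert trajectory_summary(mixed) == "mixed"

    def test_mixed_patients_and_duplicate_dates_rejected(self):
        with pytest.raises(TrajectoryError, match="patient ids"):
            score_trajectory([_visit(1, 0), _visit(2, 0, pid="P002")])
        with pytest.raises(TrajectoryError, match="duplicate"):
            score_trajectory([_visit(1, 0), _visit(1, 1)])
        with pytest.raises(TrajectoryError, match="empty"):
            score_trajectory([])


class TestPhaseDelta:
    def test_identical_phases_give_zero_deltas(self):
        visits = [_visit(1, 2, "pre"), _visit(10, 2, "post")]
        d = phase_delta(visits, "pre", "post")
        assert all(v == 0 for v in d.item_deltas.values())
        assert d.total_delta == 0

    def test_grade_change_appears_on_its_line(self):
        a = make_record(
            organ_grades=(0, 0, 3) + (0,) * 11, therapy_phase="pre",
            visit_date=datetime.date(2021, 1, 1),
        )
        b = make_record(
            organ_grades=(0, 0, 1) + (0,) * 11, therapy_phase="sirolimus",
            visit_date=datetime.date(2021, 6, 1),
        )
        d = phase_delta([a, b], "pre", "sirolimus")
        assert d.item_deltas[3] == -2
        assert d.total_delta == pytest.approx((1 - 3) * 1.5)

    def test_multi_visit_phases_use_per_phase_means(self):
        # pre: grades 4 and 2 on line 1 (mean 3); post: 1 and 0 (mean 0.5)
        visits = [
            _visit(1, 4, "pre"), _visit(2, 2, "pre"),
            _visit(10, 1, "post"), _visit(11, 0, "post"),
        ]
        d = phase_delta(visits, "pre", "post")
        assert d.item_deltas[1] == pytest.approx(0.5 - 3.0)
        assert d.total_delta == pytest.approx((0.5 - 3.0) * 1.5)

    def test_unknown_phase_label_is_a_lookup_error(self):
        with pytest.raises(KeyError):
            phase_delta([_visit(1, 0, "pre")], "pre", "post")
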