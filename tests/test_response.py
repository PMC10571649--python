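"""Per-lesion classification: RANO-BM categories, edema grades,
directions, congruence, trajectory patterns, sum of diameters."""

import itertools

import pytest

from ranovol import (AnalysisConfig, Direction, EdemaGrade, LesionMeasurement,
                     PatternLabel, ResponseCategory, assess_lesion,
                     classify_edema_grade, classify_rano_bm, congruence,
                     direction, pattern_label, patient_sum_ld)
from ranovol.cohort import followup_windows

from conftest import make_series


def meas(ld=None, core_present=True, edema=None, resolved=False, day=60):
    return LesionMeasurement(patient_id="P", lesion_id="L",
                             days_from_srt=day, ld_mm=ld,
                             edema_cm3=edema, core_present=core_present,
                             edema_resolved=resolved)


class TestRanoBM:
    def test_partial_response_at_exactly_30_percent(self):
        assert classify_rano_bm(14.0, 14.0, meas(ld=9.8)) \
            is ResponseCategory.PR

    def test_progression_at_exactly_20_percent_from_nadir(self):
        assert classify_rano_bm(14.0, 10.0, meas(ld=12.0)) \
            is ResponseCategory.PD

    def test_disappeared_core_is_complete_response(self):
        assert classify_rano_bm(14.0, 14.0, meas(core_present=False)) \
            is ResponseCategory.CR

    def test_not_previously_present_is_new(self):
        assert classify_rano_bm(None, None, meas(ld=6.0),
                                previously_present=False) \
            is ResponseCategory.NEW

    def test_no_criterion_is_stable(self):
        assert classify_rano_bm(14.0, 12.0, meas(ld=12.0)) \
            is ResponseCategory.SD

    def test_progression_trumps_response_from_deep_nadir(self):
        # 40% below baseline but 25% above nadir: progressive
        assert classify_rano_bm(20.0, 9.6, meas(ld=12.0)) \
            is ResponseCategory.PD

    def test_reappearance_after_cr_is_progression_at_any_size(self):
        assert classify_rano_bm(14.0, 0.0, meas(ld=2.0)) \
            is ResponseCategory.PD

    def test_absent_scan_yields_no_category(self):
        assert classify_rano_bm(14.0, 14.0, None) is None

    def test_category_switches_only_at_printed_thresholds(self):
        # sweep percent decrease from baseline in 0.1 steps
        decs = [i / 10 for i in range(0, 501)]
        cats = [classify_rano_bm(14.0, 14.0, meas(ld=14.0 * (1 - d / 100)))
                for d in decs]
        assert min(d for d, c in zip(decs, cats)
                   if c is ResponseCategory.PR) == 30.0
        assert all(c is ResponseCategory.SD
                   for d, c in zip(decs, cats) if d < 30.0)
        # sweep percent increase from a 10 mm nadir
        incs = [i / 10 for i in range(0, 401)]
        cats = [classify_rano_bm(14.0, 10.0, meas(ld=10.0 * (1 + p / 100)))
                for p in incs]
        assert min(p for p, c in zip(incs, cats)
                   if c is ResponseCategory.PD) == 20.0
        assert all(c is ResponseCategory.SD
                   for p, c in zip(incs, cats) if p < 20.0)


class TestEdemaGrade:
    def test_reduction_of_89_percent_is_decreased(self):
        assert classify_edema_grade(1.1, 10.0) is EdemaGrade.DECREASED

    def test_increase_of_14_percent_is_stable(self):
        assert classify_edema_grade(11.4, 10.0) is EdemaGrade.STABLE

    def test_resolved_flag_wins(self):
        assert classify_edema_grade(None, 10.0, edema_resolved=True) \
            is EdemaGrade.RESOLVED

    @pytest.mark.parametrize("current,expected", [
        (7.51, EdemaGrade.STABLE), (7.5, EdemaGrade.DECREASED),
        (12.49, EdemaGrade.STABLE), (12.5, EdemaGrade.INCREASED),
    ])
    def test_boundary_belongs_to_directional_grade(self, current, expected):
        assert classify_edema_grade(current, 10.0) is expected

    def test_zero_baseline_is_undefined(self):
        assert classify_edema_grade(5.0, 0.0) is None


class TestDirectionAndCongruence:
    @pytest.mark.parametrize("prev,cur,expected", [
        (10.0, 12.0, Direction.INCREASING),
        (10.0, 8.0, Direction.DECREASING),
        (10.0, 10.0, Direction.UNCHANGED),
    ])
    def test_direction_sign(self, prev, cur, expected):
        assert direction(prev, cur) is expected

    def test_remission_flag_wins(self):
        assert direction(5.0, 0.0, now_remitted=True) is Direction.REMITTED

    def test_epsilon_band_suppresses_small_changes(self):
        assert direction(10.0, 10.4, epsilon_pct=5.0) is Direction.UNCHANGED
        assert direction(10.0, 11.0, epsilon_pct=5.0) is Direction.INCREASING

    @pytest.mark.parametrize("core,edema,expected", [
        (Direction.DECREASING, Direction.DECREASING, "congruent"),
        (Direction.INCREASING, Direction.INCREASING, "congruent"),
        (Direction.REMITTED, Direction.REMITTED, "congruent"),
        (Direction.DECREASING, Direction.INCREASING, "incongruent"),
        (Direction.UNCHANGED, Direction.UNCHANGED, "incongruent"),
        (Direction.UNCHANGED, Direction.DECREASING, "incongruent"),
    ])
    def test_congruence_definition(self, core, edema, expected):
        assert congruence(core, edema).value == expected

    def test_congruence_is_symmetric(self):
        for a, b in itertools.product(Direction, Direction):
            assert congruence(a, b).value == congruence(b, a).value

    def test_flat_pairs_congruent_when_configured(self):
        lab = congruence(Direction.UNCHANGED, Direction.UNCHANGED,
                         unchanged_congruent=True)
        assert lab.value == "congruent"

    def test_missing_direction_gives_no_label(self):
        assert congruence(None, Direction.DECREASING) is None


class TestPatternLabel:
    @pytest.mark.parametrize("values,expected", [
        ([100, 40, 20, 8], PatternLabel.CONTINUOUS_DECREASE),
        ([100, 30, 60, 25], PatternLabel.WAXING_WANING),
        ([100, 114, 130, 396], PatternLabel.CONTINUOUS_INCREASE),
        ([100, 50, 20, 0], PatternLabel.COMPLETE_REMISSION),
        ([100, 130, 70, 50], PatternLabel.PARADOXICAL_THEN_DECREASE),
        ([100, 130, 70, 90, 50], PatternLabel.OTHER),  # late bump > start
        ([100, 40, 70, 30, 60], PatternLabel.WAXING_WANING),
    ])
    def test_pattern_taxonomy(self, values, expected):
        assert pattern_label(values).label is expected

    def test_insufficient_followups_noted(self):
        res = pattern_label([100, 50])
        assert res.label is PatternLabel.OTHER
        assert "insufficient" in res.note

    def test_waxing_never_exceeds_baseline(self):
        # the transient regrowth tops the pretreatment value: not waxing
        assert pattern_label([100, 60, 120, 50]).label is PatternLabel.OTHER

    def test_every_series_gets_exactly_one_label(self, rng):
        for _ in range(200):
            vals = [100.0] + list(rng.uniform(0, 300, size=rng.integers(2, 8)))
            res = pattern_label(vals)
            assert isinstance(res.label, PatternLabel)


class TestPatientSumLD:
    def _series_set(self, lds, scans_by_lesion=None):
        out = []
        for i, ld in enumerate(lds):
            scans = (scans_by_lesion or {}).get(i, [])
            out.append(make_series(baseline_ld=ld, lesion=f"L{i}",
                                   scans=scans))
        return out

    def test_five_largest_of_six_sum_at_baseline(self):
        series = self._series_set([14, 12, 11, 10, 10, 9])
        assert patient_sum_ld(series, None) == 57.0

    def test_cap_never_exceeds_five_lesions(self):
        series = self._series_set([20, 19, 18, 17, 16, 15, 14, 13])
        assert patient_sum_ld(series, None) == 20 + 19 + 18 + 17 + 16

    def test_three_measurable_sum_over_three(self):
        series = self._series_set([14, 12, 11, 9, 8])
        assert patient_sum_ld(series, None) == 37.0

    def test_cr_target_contributes_zero(self):
        series = self._series_set(
            [14, 12], {0: [(60, "CR", None)], 1: [(60, 12.0, None)]})
        w1 = followup_windows()[0]
        assert patient_sum_ld(series, w1) == 12.0

    def test_missing_scan_makes_sum_undefined(self):
        series = self._series_set([14, 12], {0: [(60, 10.0, None)]})
        assert patient_sum_ld(series, followup_windows()[0]) is None

    def test_no_measurable_lesion_undefined(self):
        assert patient_sum_ld(self._series_set([9, 8]), None) is None

    def test_recorded_small_perpendicular_disqualifies(self):
        s = make_series(baseline_ld=14.0)
        s.baseline_perp_mm = 4.0
        assert patient_sum_ld([s], None) is None


class TestAssessLesion:
    def test_constant_series_is_stable_and_incongruent(self):
        s = make_series(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 14.0, 10.0), (150, 14.0, 10.0)])
        a = assess_lesion(s)
        assert len(a.windows) == 2
        for w in a.windows:
            assert w.rano is ResponseCategory.SD
            assert w.edema_grade is EdemaGrade.STABLE
            assert w.core_direction is Direction.UNCHANGED
            assert w.congruence == "incongruent"

    def test_incongruent_first_followup_flag(self):
        s = make_series(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 10.0, 15.0), (150, 9.0, 13.0)])
        a = assess_lesion(s)
        assert a.windows[0].congruence == "incongruent"
        assert a.incongruent_at_first_followup is True
        assert a.windows[1].congruence == "congruent"

    def test_fully_decreasing_series_congruent_everywhere(self):
        s = make_series(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 10.0, 6.0), (150, 8.0, 3.0),
                               (250, 6.0, 1.0)])
        a = assess_lesion(s)
        assert all(w.congruence == "congruent" for w in a.windows)
        assert a.incongruent_at_first_followup is False
        assert a.edema_pattern.label is PatternLabel.CONTINUOUS_DECREASE

    def test_empty_followups_give_empty_assessment(self):
        a = assess_lesion(make_series())
        assert a.windows == []
        assert a.incongruent_at_first_followup is None

    def test_confluent_lesion_keeps_core_labels_only(self):
        s = make_series(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 10.0, 6.0), (150, 8.0, 3.0)],
                        confluent_edema=True)
        a = assess_lesion(s)
        assert all(w.rano is not None for w in a.windows)
        assert all(w.edema_grade is None and w.congruence is None
                   for w in a.windows)

    def test_direction_uses_previous_timepoint_not_baseline(self):
        # LD: 14 -> 8 (down) -> 10 (up, though still below baseline)
        s = make_series(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 8.0, 5.0), (150, 10.0, 7.0)])
        a = assess_lesion(s)
        assert a.windows[1].core_direction is Direction.INCREASING
        assert a.windows[1].edema_direction is Direction.INCREASING

    def test_thresholds_are_configurable(self):
        cfg = AnalysisConfig(pr_pct=50.0)
        s = make_series(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 9.0, 10.0)])
        a = assess_lesion(s, config=cfg)
        assert a.windows[0].rano is ResponseCategory.SD  # -36% < 50%
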