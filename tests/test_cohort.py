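"""Longitudinal cohort model: windows, baselines, nadir, exclusions, I/O."""

import numpy as np
import pandas as pd
import pytest

from ranovol import (apply_exclusions, assign_window, build_series, nadir_ld,
                     read_cohort_csv, relative_size,
                     select_window_measurement, write_cohort_csv)
from ranovol.cohort import (SCHEMA_COLUMNS, followup_windows,
                            validate_cohort_table)

from conftest import make_series


class TestWindows:
    @pytest.mark.parametrize("day,label", [
        (45, "W1"), (90, "W1"), (91, "W2"), (180, "W2"), (181, "W3"),
        (270, "W3"), (271, "W4"), (365, "W4"), (366, "W5"), (400, "W5"),
        (10_000, "W5"),
    ])
    def test_assignment_is_total_and_right_closed(self, day, label):
        assert assign_window(day).label == label

    @pytest.mark.parametrize("day", [0, -5])
    def test_baseline_days_are_not_followup(self, day):
        with pytest.raises(ValueError, match="not a follow-up"):
            assign_window(day)

    def test_windows_are_disjoint_and_exhaustive(self):
        wins = followup_windows()
        for day in range(1, 800):
            assert sum(w.contains(day) for w in wins) == 1

    def test_earliest_scan_selected_within_window(self):
        s = make_series(scans=[(40, 12.0, 5.0), (80, 11.0, 4.0)])
        m = select_window_measurement(s, followup_windows()[0])
        assert m.days_from_srt == 40

    def test_no_scan_in_window_gives_none(self):
        s = make_series(scans=[(40, 12.0, 5.0)])
        assert select_window_measurement(s, followup_windows()[2]) is None

    def test_two_scans_in_second_window(self):
        s = make_series(scans=[(100, 12.0, 5.0), (170, 11.0, 4.0)])
        m = select_window_measurement(s, followup_windows()[1])
        assert m.days_from_srt == 100


class TestRelativeSize:
    def test_fraction_of_baseline_in_percent(self):
        assert relative_size(3.0, 8.1) == pytest.approx(100 * 3 / 8.1)

    def test_identity_is_exactly_100(self):
        for b in (0.3, 8.1, 14.0, 123.4):
            assert relative_size(b, b) == 100.0

    def test_zero_current_is_zero_percent(self):
        assert relative_size(0.0, 5.0) == 0.0

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError):
            relative_size(3.0, 0.0)


class TestNadir:
    def test_minimum_over_prefix(self):
        s = make_series(baseline_ld=14.0,
                        scans=[(60, 10.0, None), (150, 12.0, None)])
        assert nadir_ld(s, 150) == 10.0

    def test_no_followups_gives_baseline(self):
        s = make_series(baseline_ld=14.0)
        assert nadir_ld(s, 100) == 14.0

    def test_running_minimum(self):
        s = make_series(baseline_ld=14.0,
                        scans=[(60, 15.0, None), (150, 13.0, None)])
        assert nadir_ld(s, 200) == 13.0

    def test_non_increasing_in_horizon(self):
        s = make_series(baseline_ld=14.0,
                        scans=[(60, 12.0, None), (150, 9.0, None),
                               (250, 11.0, None)])
        vals = [nadir_ld(s, d) for d in (59, 60, 150, 250, 400)]
        assert vals == sorted(vals, reverse=True)

    def test_complete_response_pulls_nadir_to_zero_when_asked(self):
        s = make_series(baseline_ld=14.0,
                        scans=[(60, "CR", None), (150, 5.0, None)])
        assert nadir_ld(s, 100) == 14.0
        assert nadir_ld(s, 100, post_cr_zero=True) == 0.0


class TestExclusions:
    def _series(self, **kw):
        defaults = dict(baseline_ld=14.0, baseline_edema=10.0,
                        scans=[(60, 12.0, 8.0)])
        defaults.update({k: kw.pop(k) for k in list(kw)
                         if k in ("baseline_ld", "scans")})
        return make_series(**defaults, **kw)

    def test_small_baseline_excluded_by_rule_5(self):
        s = self._series(baseline_ld=9.0, lesion="small")
        res = apply_exclusions([s])
        assert res.ld_series == []
        assert list(res.log["rule"]) == ["5_baseline_ld"]

    def test_thick_slices_excluded_by_rule_3(self):
        s = self._series(lesion="thick", slice_thickness_mm=3.0)
        res = apply_exclusions([s])
        assert res.ld_series == []
        assert list(res.log["rule"]) == ["3_slice_or_flair"]

    def test_missing_flair_excluded_by_rule_3(self):
        s = self._series(lesion="noflair", flair_available=False)
        res = apply_exclusions([s])
        assert list(res.log["rule"]) == ["3_slice_or_flair"]

    def test_non_nsclc_excluded_by_rule_4(self):
        s = self._series(lesion="melanoma", histology="melanoma")
        res = apply_exclusions([s])
        assert list(res.log["rule"]) == ["4_histology"]

    def test_first_matching_rule_wins(self):
        # violates rule 3 AND rule 5: logged under rule 3 only
        s = self._series(baseline_ld=8.0, lesion="both",
                         slice_thickness_mm=4.0)
        res = apply_exclusions([s])
        assert list(res.log["rule"]) == ["3_slice_or_flair"]

    def test_confluent_edema_stays_in_ld_leaves_edema(self):
        s = self._series(lesion="conf", confluent_edema=True)
        res = apply_exclusions([s])
        assert len(res.ld_series) == 1
        assert res.edema_series == []
        row = res.log.iloc[0]
        assert row["rule"] == "confluent_edema"
        assert row["scope"] == "edema_only"

    def test_idempotent(self):
        series = [self._series(lesion="a"),
                  self._series(baseline_ld=9.0, lesion="b"),
                  self._series(lesion="c", confluent_edema=True)]
        res1 = apply_exclusions(series)
        res2 = apply_exclusions(res1.ld_series)
        assert {s.lesion_id for s in res2.ld_series} == \
            {s.lesion_id for s in res1.ld_series}
        # confluent restriction is re-logged but removes nothing further
        assert all(res2.log["scope"] == "edema_only")

    def test_each_excluded_lesion_logged_exactly_once(self):
        series = [self._series(baseline_ld=9.0, lesion=f"x{i}")
                  for i in range(4)]
        res = apply_exclusions(series)
        assert len(res.log) == 4
        assert res.log["lesion_id"].is_unique


class TestSeriesAssemblyAndIO:
    def _table(self):
        rows = [
            # pre-SRT edema baselines: day -20 and a later day -5 (chosen)
            dict(patient_id="P1", lesion_id="L1", days_from_srt=-20,
                 edema_cm3=9.0),
            dict(patient_id="P1", lesion_id="L1", days_from_srt=-5,
                 edema_cm3=8.0),
            dict(patient_id="P1", lesion_id="L1", days_from_srt=0,
                 ld_mm=14.0, perp_mm=8.0),
            dict(patient_id="P1", lesion_id="L1", days_from_srt=50,
                 ld_mm=10.0, perp_mm=6.0, edema_cm3=4.0),
            # a new lesion: first appears at day 120
            dict(patient_id="P1", lesion_id="L2", days_from_srt=120,
                 ld_mm=6.0, perp_mm=4.0, edema_cm3=2.0),
            dict(patient_id="P1", lesion_id="L2", days_from_srt=200,
                 ld_mm=9.0, perp_mm=5.0, edema_cm3=4.0),
        ]
        base = dict(ld_mm=None, perp_mm=None, edema_cm3=None,
                    core_present=True, edema_resolved=False,
                    confluent_edema=False, on_steroids=False,
                    slice_thickness_mm=1.0, flair_available=True,
                    histology="NSCLC")
        return pd.DataFrame([{**base, **r} for r in rows],
                            columns=SCHEMA_COLUMNS)

    def test_baselines_derived_from_day0_and_latest_presrt(self):
        s1, s2 = build_series(self._table())
        assert s1.baseline_ld_mm == 14.0
        assert s1.baseline_edema_cm3 == 8.0  # latest pre-SRT scan wins
        assert not s1.is_new_lesion

    def test_new_lesion_uses_first_appearance_as_baseline(self):
        _, s2 = build_series(self._table())
        assert s2.is_new_lesion
        assert s2.appearance_day == 120
        assert s2.baseline_ld_mm == 6.0
        assert [m.days_from_srt for m in s2.followups()] == [200]

    def test_csv_roundtrip_preserves_values(self, tmp_path):
        df = self._table()
        path = tmp_path / "cohort.csv"
        write_cohort_csv(df, path)
        back = read_cohort_csv(path)
        assert list(back.columns) == SCHEMA_COLUMNS
        assert len(back) == len(df)
        assert back["ld_mm"].dropna().tolist() == [14.0, 10.0, 6.0, 9.0]
        assert back["core_present"].all()

    def test_validation_reports_row_numbers(self):
        df = self._table()
        df.loc[3, "ld_mm"] = -1.0
        errors = validate_cohort_table(df)
        assert any("row 4" in e and "ld_mm" in e for e in errors)

    def test_validation_missing_columns(self):
        errors = validate_cohort_table(pd.DataFrame({"patient_id": []}))
        assert errors and "missing columns" in errors[0]
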