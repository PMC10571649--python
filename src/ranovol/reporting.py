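"""End-to-end cohort analysis: exclusions -> series assembly ->
per-lesion assessment -> congruence ratios, window summaries and
cohort statistics, with flat CSV/JSON exports.

Every statistic is reported with its n, because the number of lesions
contributing differs window by window (scans are missing at the
defined timepoints for many lesions), and any reproduction must expose
its own denominators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .cohort import (LesionSeries, apply_exclusions, build_series,
                     followup_windows, select_window_measurement)
from .config import AnalysisConfig
from .response import LesionAssessment, assess_lesion
from .stats import (paired_signed_rank, rank_correlation,
                    stratified_summaries, window_summary)

__all__ = ["CohortAnalysis", "analyze_cohort"]


@dataclass
class CohortAnalysis:
    """All outputs of one cohort analysis run."""

    config: AnalysisConfig
    assessments: List[LesionAssessment]
    labels: pd.DataFrame            # one row per lesion-window
    curves: pd.DataFrame            # response-curve table (relative sizes)
    congruence_by_window: pd.DataFrame
    window_summaries: pd.DataFrame
    tests: pd.DataFrame
    steroid_summaries: pd.DataFrame
    exclusion_log: pd.DataFrame
    pattern_counts: pd.DataFrame
    n_lesions_ld: int = 0
    n_lesions_edema: int = 0
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None
    spearman_n: int = 0

    def to_report_dict(self) -> dict:
        return {
            "config": json.loads(self.config.to_json()),
            "n_lesions_ld_analysis": self.n_lesions_ld,
            "n_lesions_edema_analysis": self.n_lesions_edema,
            "congruence_by_window":
                self.congruence_by_window.to_dict(orient="records"),
            "pattern_counts": self.pattern_counts.to_dict(orient="records"),
            "window_summaries":
                self.window_summaries.to_dict(orient="records"),
            "tests": self.tests.to_dict(orient="records"),
            "steroid_summaries":
                self.steroid_summaries.to_dict(orient="records"),
            "spearman": {"rho": self.spearman_rho, "p": self.spearman_p,
                         "n_pairs": self.spearman_n},
            "exclusions": self.exclusion_log.to_dict(orient="records"),
        }

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(self.to_report_dict(), indent=2, default=_jsonable))
        self.labels.to_csv(out / "lesion_window_labels.csv", index=False)
        self.curves.to_csv(out / "response_curves.csv", index=False)
        self.congruence_by_window.to_csv(
            out / "congruence_by_window.csv", index=False)
        self.window_summaries.to_csv(
            out / "window_summaries.csv", index=False)
        self.tests.to_csv(out / "tests.csv", index=False)
        self.steroid_summaries.to_csv(
            out / "steroid_summaries.csv", index=False)
        self.exclusion_log.to_csv(out / "exclusions.csv", index=False)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _enum_val(x) -> Optional[str]:
    return None if x is None else getattr(x, "value", x)


def analyze_cohort(df: pd.DataFrame,
                   config: Optional[AnalysisConfig] = None) -> CohortAnalysis:
    """Run the full response-assessment pipeline on a cohort table.

    Steps: eligibility exclusions (with a per-lesion log), series
    assembly with baselines, per-lesion per-window assessment,
    congruence ratios per window, median/IQR summaries of the relative
    LD and relative edema volume per window, paired signed-rank tests
    of baseline vs each window (absolute values, paired by lesion) and
    between consecutive windows (on the lesions present in both),
    pooled Spearman correlation of LD vs edema volume over all
    lesion-timepoints, and steroid-stratified summaries.
    """
    cfg = config or AnalysisConfig()
    series_all = build_series(df)
    excl = apply_exclusions(series_all)
    edema_ok = {(s.patient_id, s.lesion_id) for s in excl.edema_series}

    windows = followup_windows(cfg.window_edges_days)
    assessments: List[LesionAssessment] = []
    label_rows: List[dict] = []
    curve_rows: List[dict] = []
    # per-window absolute values, keyed by lesion for pairing
    ld_by_window: Dict[str, Dict[tuple, float]] = {w.label: {} for w in windows}
    ed_by_window: Dict[str, Dict[tuple, float]] = {w.label: {} for w in windows}
    base_ld: Dict[tuple, float] = {}
    base_ed: Dict[tuple, float] = {}

    for s in excl.ld_series:
        key = (s.patient_id, s.lesion_id)
        a = assess_lesion(s, config=cfg, include_edema=key in edema_ok)
        assessments.append(a)
        if s.baseline_ld_mm is not None and not s.is_new_lesion:
            base_ld[key] = s.baseline_ld_mm
        if (key in edema_ok and s.baseline_edema_cm3 is not None
                and not s.is_new_lesion):
            base_ed[key] = s.baseline_edema_cm3
        for w in windows:
            m = select_window_measurement(s, w)
            if m is None:
                continue
            if m.ld_mm is not None:
                ld_by_window[w.label][key] = m.ld_mm
            elif not m.core_present:
                ld_by_window[w.label][key] = 0.0
            if key in edema_ok:
                v = 0.0 if m.edema_resolved else m.edema_cm3
                if v is not None:
                    ed_by_window[w.label][key] = v
        for wa in a.windows:
            label_rows.append({
                "patient_id": s.patient_id, "lesion_id": s.lesion_id,
                "window": wa.window, "days_from_srt": wa.days_from_srt,
                "rano": _enum_val(wa.rano),
                "edema_grade": _enum_val(wa.edema_grade),
                "core_direction": _enum_val(wa.core_direction),
                "edema_direction": _enum_val(wa.edema_direction),
                "congruence": wa.congruence})
            curve_rows.append({
                "patient_id": s.patient_id, "lesion_id": s.lesion_id,
                "window": wa.window, "days_from_srt": wa.days_from_srt,
                "relative_ld_pct": wa.relative_ld_pct,
                "relative_edema_pct": wa.relative_edema_pct})

    labels = pd.DataFrame(label_rows, columns=[
        "patient_id", "lesion_id", "window", "days_from_srt", "rano",
        "edema_grade", "core_direction", "edema_direction", "congruence"])
    curves = pd.DataFrame(curve_rows, columns=[
        "patient_id", "lesion_id", "window", "days_from_srt",
        "relative_ld_pct", "relative_edema_pct"])

    # congruence ratio per window
    cong_rows = []
    for w in windows:
        sub = labels[(labels["window"] == w.label)
                     & labels["congruence"].notna()]
        n = len(sub)
        n_inc = int((sub["congruence"] == "incongruent").sum())
        cong_rows.append({
            "window": w.label, "n": n, "n_congruent": n - n_inc,
            "n_incongruent": n_inc,
            "pct_incongruent": 100.0 * n_inc / n if n else np.nan})
    congruence_by_window = pd.DataFrame(cong_rows)

    # window summaries of relative sizes
    sum_rows = []
    for var in ("relative_ld_pct", "relative_edema_pct"):
        for w in windows:
            vals = curves.loc[curves["window"] == w.label, var].dropna()
            if len(vals) == 0:
                continue
            s_ = window_summary(vals, window=w.label)
            sum_rows.append({"variable": var, "window": w.label, "n": s_.n,
                             "median": s_.median, "q1": s_.q1, "q3": s_.q3})
    window_summaries = pd.DataFrame(
        sum_rows, columns=["variable", "window", "n", "median", "q1", "q3"])

    # paired tests: baseline vs window, and consecutive windows
    test_rows = []
    for var, by_w, base in (("ld_mm", ld_by_window, base_ld),
                            ("edema_cm3", ed_by_window, base_ed)):
        for w in windows:
            common = sorted(set(by_w[w.label]) & set(base))
            if len(common) < 2:
                continue
            res = paired_signed_rank([base[k] for k in common],
                                     [by_w[w.label][k] for k in common])
            test_rows.append({
                "variable": var, "comparison": f"baseline_vs_{w.label}",
                "n": res.n[0], "statistic": res.statistic,
                "p_value": res.p_value, "method": res.method})
        for wa, wb in zip(windows, windows[1:]):
            common = sorted(set(by_w[wa.label]) & set(by_w[wb.label]))
            if len(common) < 2:
                continue
            res = paired_signed_rank([by_w[wa.label][k] for k in common],
                                     [by_w[wb.label][k] for k in common])
            test_rows.append({
                "variable": var,
                "comparison": f"{wa.label}_vs_{wb.label}",
                "n": res.n[0], "statistic": res.statistic,
                "p_value": res.p_value, "method": res.method})
    tests = pd.DataFrame(test_rows, columns=[
        "variable", "comparison", "n", "statistic", "p_value", "method"])

    # pooled Spearman over all lesion-timepoints with both measurements
    edema_keys = df.apply(
        lambda r: (str(r["patient_id"]), str(r["lesion_id"])) in edema_ok,
        axis=1) if len(df) else pd.Series([], dtype=bool)
    pooled = df[edema_keys] if len(df) else df
    pooled = pooled[pooled["ld_mm"].notna() & pooled["edema_cm3"].notna()]
    rho = p = None
    n_pairs = len(pooled)
    if n_pairs >= 3:
        res = rank_correlation(pooled["ld_mm"], pooled["edema_cm3"])
        rho, p = res.rho, res.p_value

    # steroid stratification of relative edema, per window (descriptive)
    ster_rows = df.merge(curves, on=["patient_id", "lesion_id",
                                     "days_from_srt"], how="inner")
    ster_rows = ster_rows[ster_rows["relative_edema_pct"].notna()]
    if len(ster_rows):
        steroid_summaries = stratified_summaries(
            ster_rows, "relative_edema_pct", "on_steroids",
            window_col="window")
    else:
        steroid_summaries = pd.DataFrame(
            columns=["window", "group", "n", "median", "q1", "q3", "p_value"])

    # edema pattern counts over assessed lesions
    pat_counts: Dict[str, int] = {}
    for a in assessments:
        if (a.patient_id, a.lesion_id) in edema_ok:
            pat_counts[a.edema_pattern.label.value] = \
                pat_counts.get(a.edema_pattern.label.value, 0) + 1
    pattern_counts = pd.DataFrame(
        sorted(pat_counts.items()), columns=["pattern", "n"])

    return CohortAnalysis(
        config=cfg, assessments=assessments, labels=labels, curves=curves,
        congruence_by_window=congruence_by_window,
        window_summaries=window_summaries, tests=tests,
        steroid_summaries=steroid_summaries, exclusion_log=excl.log,
        pattern_counts=pattern_counts,
        n_lesions_ld=len(excl.ld_series),
        n_lesions_edema=len(excl.edema_series),
        spearman_rho=rho, spearman_p=p, spearman_n=n_pairs)
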