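"""Per-lesion response classification and core-vs-edema congruence.

Implements lesion-level RANO-BM categories (CR / PR / SD / PD / NEW),
a four-level peritumoral-edema volume grading (stable within a +/-25 %
band, decreased, increased, resolved), trajectory direction labels and
the congruence of core vs edema response curves, trajectory pattern
labelling, and the patient-level sum of longest diameters over up to
five target lesions.

Classification order for RANO-BM follows the usual precedence:
new lesion, then complete response, then progression (>=20 % LD
increase from nadir, so a lesion regrowing from a deep nadir is
progressive even while still well below baseline), then partial
response (>=30 % LD decrease from baseline), else stable disease.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import List, Optional, Sequence

from .cohort import (FollowUpWindow, LesionMeasurement, LesionSeries,
                     followup_windows, nadir_ld, select_window_measurement)
from .config import AnalysisConfig

__all__ = [
    "ResponseCategory", "EdemaGrade", "Direction", "PatternLabel",
    "CongruenceLabel", "PatternResult", "ResponseAssessment",
    "LesionAssessment", "classify_rano_bm", "classify_edema_grade",
    "direction", "congruence", "pattern_label", "patient_sum_ld",
    "assess_lesion",
]


# tolerance absorbing float representation error in percent-change
# comparisons, so an exactly-at-threshold measurement (e.g. 9.8 mm from a
# 14 mm baseline: a 30 % decrease) lands on the inclusive side
_FP_TOL = 1e-9


class ResponseCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NEW = "NEW"


class EdemaGrade(str, Enum):
    STABLE = "stable"
    DECREASED = "decreased"
    INCREASED = "increased"
    RESOLVED = "resolved"


class Direction(str, Enum):
    INCREASING = "increasing"
    DECREASING = "decreasing"
    REMITTED = "remitted"
    UNCHANGED = "unchanged"


class PatternLabel(str, Enum):
    CONTINUOUS_DECREASE = "continuous_decrease"
    WAXING_WANING = "waxing_waning"
    PARADOXICAL_THEN_DECREASE = "paradoxical_then_decrease"
    CONTINUOUS_INCREASE = "continuous_increase"
    COMPLETE_REMISSION = "complete_remission"
    OTHER = "other"


@dataclass(frozen=True)
class CongruenceLabel:
    """Congruent iff core and edema move in the same direction and that
    direction is increasing, decreasing or remitted; any pair involving
    'unchanged' (unless configured otherwise) and any unequal pair is
    incongruent."""

    value: str  # "congruent" | "incongruent"
    core_direction: Direction
    edema_direction: Direction


@dataclass(frozen=True)
class PatternResult:
    label: PatternLabel
    note: Optional[str] = None


def classify_rano_bm(baseline_ld: Optional[float],
                     nadir_ld_mm: Optional[float],
                     current: Optional[LesionMeasurement],
                     previously_present: bool = True, *,
                     pr_pct: float = 30.0,
                     pd_pct: float = 20.0) -> Optional[ResponseCategory]:
    """RANO-BM-style category for one lesion at one timepoint.

    Evaluation order: NEW (not present on any prior scan) -> CR (core
    disappeared) -> PD (LD increase from nadir >= ``pd_pct`` %, or any
    reappearance after CR, i.e. nadir 0) -> PR (LD decrease from
    baseline >= ``pr_pct`` %) -> SD.  Both thresholds are inclusive.
    ``current`` absent means no scan: returns None, never CR.
    """
    if current is None:
        return None
    if not previously_present:
        return ResponseCategory.NEW
    if not current.core_present:
        return ResponseCategory.CR
    ld = current.ld_mm
    if ld is None:
        return None
    if nadir_ld_mm is not None:
        if nadir_ld_mm == 0:
            # reappearance after complete response: progression at any size
            return ResponseCategory.PD
        if 100.0 * (ld - nadir_ld_mm) / nadir_ld_mm >= pd_pct - _FP_TOL:
            return ResponseCategory.PD
    if baseline_ld is not None and baseline_ld > 0:
        if 100.0 * (baseline_ld - ld) / baseline_ld >= pr_pct - _FP_TOL:
            return ResponseCategory.PR
    return ResponseCategory.SD


def classify_edema_grade(current_cm3: Optional[float],
                         baseline_cm3: Optional[float],
                         edema_resolved: bool = False, *,
                         band_pct: float = 25.0) -> Optional[EdemaGrade]:
    """Edema-volume grade relative to the pre-treatment baseline.

    Resolved if the edema has disappeared; otherwise stable when the
    percent change lies strictly inside the +/- ``band_pct`` band, and
    decreased / increased at or beyond the boundary (the boundary
    belongs to the directional grade).  Undefined (None) when the
    baseline is missing or zero.
    """
    if edema_resolved or (current_cm3 is not None and current_cm3 == 0):
        return EdemaGrade.RESOLVED
    if current_cm3 is None or baseline_cm3 is None or baseline_cm3 <= 0:
        return None
    delta = 100.0 * (current_cm3 - baseline_cm3) / baseline_cm3
    if abs(delta) < band_pct - _FP_TOL:
        return EdemaGrade.STABLE
    return EdemaGrade.DECREASED if delta < 0 else EdemaGrade.INCREASED


def direction(previous: Optional[float], current: Optional[float],
              now_remitted: bool = False, *,
              epsilon_pct: float = 0.0) -> Optional[Direction]:
    """Trajectory direction between two consecutive timepoints.

    Remitted when the quantity has disappeared; else increasing or
    decreasing when the relative change exceeds ``epsilon_pct`` percent
    in magnitude, unchanged otherwise.  A quantity reappearing from a
    remitted state (previous 0) counts as increasing.
    """
    if now_remitted or (current is not None and current == 0):
        return Direction.REMITTED
    if current is None:
        return None
    if previous is None:
        return None
    if previous == 0:
        return Direction.INCREASING if current > 0 else Direction.REMITTED
    change = 100.0 * (current - previous) / previous
    if change > epsilon_pct:
        return Direction.INCREASING
    if change < -epsilon_pct:
        return Direction.DECREASING
    return Direction.UNCHANGED


_CONGRUENT_DIRECTIONS = {Direction.INCREASING, Direction.DECREASING,
                         Direction.REMITTED}


def congruence(core_dir: Optional[Direction],
               edema_dir: Optional[Direction], *,
               unchanged_congruent: bool = False
               ) -> Optional[CongruenceLabel]:
    """Congruence of the core and edema response curves at one timepoint.

    Symmetric in its arguments.  With the strict definition (default),
    a pair of 'unchanged' directions is incongruent; set
    ``unchanged_congruent`` to treat flat pairs as congruent.
    Returns None when either direction is unavailable.
    """
    if core_dir is None or edema_dir is None:
        return None
    same = core_dir == edema_dir
    ok = same and (core_dir in _CONGRUENT_DIRECTIONS
                   or (unchanged_congruent and core_dir == Direction.UNCHANGED))
    return CongruenceLabel(value="congruent" if ok else "incongruent",
                           core_direction=core_dir, edema_direction=edema_dir)


def pattern_label(values: Sequence[float],
                  baseline: float = 100.0) -> PatternResult:
    """Classify a whole trajectory of relative sizes into a pattern.

    ``values`` is the time-ordered series of relative sizes (percent of
    baseline) starting with the baseline itself (100).  Requires at
    least two follow-up values; fewer yield OTHER with a note.

    Precedence (first match wins):

    1. complete_remission — final value 0 (quantity disappeared);
    2. continuous_decrease — every successive change <= 0;
    3. continuous_increase — every successive change >= 0 and final
       above baseline;
    4. paradoxical_then_decrease — first change up, second down, all
       later changes <= 0;
    5. waxing_waning — a decrease, then at least one increase, then a
       later decrease, the series never exceeding baseline;
    6. other.
    """
    vals = [float(v) for v in values]
    if len(vals) < 3:  # baseline + at least two follow-ups
        return PatternResult(PatternLabel.OTHER, "insufficient timepoints")
    changes = [b - a for a, b in zip(vals, vals[1:])]
    if vals[-1] == 0:
        return PatternResult(PatternLabel.COMPLETE_REMISSION)
    if all(c <= 0 for c in changes):
        return PatternResult(PatternLabel.CONTINUOUS_DECREASE)
    if all(c >= 0 for c in changes) and vals[-1] > baseline:
        return PatternResult(PatternLabel.CONTINUOUS_INCREASE)
    if (changes[0] > 0 and changes[1] < 0
            and all(c <= 0 for c in changes[2:])):
        return PatternResult(PatternLabel.PARADOXICAL_THEN_DECREASE)
    if max(vals) <= baseline:
        # look for decrease ... increase ... decrease
        for i, ci in enumerate(changes):
            if ci >= 0:
                continue
            for j in range(i + 1, len(changes)):
                if changes[j] <= 0:
                    continue
                if any(c < 0 for c in changes[j + 1:]):
                    return PatternResult(PatternLabel.WAXING_WANING)
            break
    return PatternResult(PatternLabel.OTHER)


def patient_sum_ld(series_list: Sequence[LesionSeries],
                   window: Optional[FollowUpWindow], *,
                   config: Optional[AnalysisConfig] = None) -> Optional[float]:
    """Sum of longest diameters over the patient's target lesions.

    Target lesions are the up-to-five largest lesions measurable at
    baseline (LD >= 10 mm; a recorded perpendicular < 5 mm disqualifies,
    a missing perpendicular does not), fixed thereafter.  ``window``
    None means the baseline sum.  A complete-response lesion contributes
    0; a target lesion without a scan in the window makes the sum
    undefined (None), as does having no measurable lesion at all.
    """
    cfg = config or AnalysisConfig()
    eligible = []
    for s in series_list:
        ld = s.baseline_ld_mm
        if ld is None or ld < cfg.measurable_ld_mm:
            continue
        if (s.baseline_perp_mm is not None
                and s.baseline_perp_mm < cfg.measurable_perp_mm):
            continue
        eligible.append(s)
    if not eligible:
        return None
    eligible.sort(key=lambda s: (-s.baseline_ld_mm, s.lesion_id))
    targets = eligible[:cfg.max_target_lesions]
    if window is None:
        return float(sum(s.baseline_ld_mm for s in targets))
    total = 0.0
    for s in targets:
        m = select_window_measurement(s, window)
        if m is None:
            return None
        if not m.core_present:
            continue  # CR contributes 0
        if m.ld_mm is None:
            return None
        total += m.ld_mm
    return float(total)


@dataclass
class ResponseAssessment:
    """All labels for one lesion in one follow-up window."""

    window: str
    days_from_srt: int
    rano: Optional[ResponseCategory]
    edema_grade: Optional[EdemaGrade]
    core_direction: Optional[Direction]
    edema_direction: Optional[Direction]
    congruence: Optional[str]
    relative_ld_pct: Optional[float]
    relative_edema_pct: Optional[float]


@dataclass
class LesionAssessment:
    """Series-level assessment: one window row per available scan plus
    whole-trajectory pattern labels and the early-congruence flag."""

    patient_id: str
    lesion_id: str
    windows: List[ResponseAssessment] = field(default_factory=list)
    core_pattern: PatternResult = field(
        default_factory=lambda: PatternResult(PatternLabel.OTHER))
    edema_pattern: PatternResult = field(
        default_factory=lambda: PatternResult(PatternLabel.OTHER))
    incongruent_at_first_followup: Optional[bool] = None


def _edema_value(m: LesionMeasurement) -> Optional[float]:
    if m.edema_resolved:
        return 0.0
    return m.edema_cm3


def assess_lesion(series: LesionSeries, *,
                  config: Optional[AnalysisConfig] = None,
                  include_edema: bool = True) -> LesionAssessment:
    """Full per-lesion assessment across the follow-up windows.

    For each window with a scan (earliest scan if several): the RANO-BM
    category (against the running nadir over strictly earlier scans),
    the edema grade against the pre-treatment edema baseline, direction
    labels for core LD and edema volume against the previous available
    selected timepoint (baseline for the first), and the congruence
    label.  Windows without a scan are simply absent from the output.

    Series-level outputs: pattern labels for the core-LD and
    edema-volume trajectories over all follow-up scans, and whether the
    lesion was incongruent at its first available follow-up window (a
    candidate early marker of subsequent progression).

    ``include_edema=False`` suppresses edema grading, edema directions
    and congruence — used for lesions whose confluent edema cannot be
    attributed to a single core.
    """
    cfg = config or AnalysisConfig()
    if include_edema and series.confluent_edema:
        include_edema = False
    out = LesionAssessment(patient_id=series.patient_id,
                           lesion_id=series.lesion_id)

    baseline_ld = series.baseline_ld_mm
    baseline_edema = series.baseline_edema_cm3
    prev_ld: Optional[float] = baseline_ld
    prev_edema: Optional[float] = baseline_edema
    seen_any_scan = not series.is_new_lesion
    first_labelled = True

    for w in followup_windows(cfg.window_edges_days):
        m = select_window_measurement(series, w)
        if m is None:
            continue
        nad = nadir_ld(series, m.days_from_srt - 1, post_cr_zero=True)
        rano = classify_rano_bm(baseline_ld, nad, m,
                                previously_present=seen_any_scan,
                                pr_pct=cfg.pr_pct, pd_pct=cfg.pd_pct)
        core_dir = direction(prev_ld, m.ld_mm,
                             now_remitted=not m.core_present,
                             epsilon_pct=cfg.direction_epsilon_pct)
        rel_ld = None
        if (m.ld_mm is not None and baseline_ld and baseline_ld > 0
                and not (series.is_new_lesion
                         and m.days_from_srt == series.appearance_day)):
            rel_ld = 100.0 * m.ld_mm / baseline_ld

        grade = edema_dir = rel_edema = None
        cong = None
        if include_edema:
            cur_edema = _edema_value(m)
            grade = classify_edema_grade(m.edema_cm3, baseline_edema,
                                         m.edema_resolved,
                                         band_pct=cfg.edema_band_pct)
            edema_dir = direction(prev_edema, cur_edema,
                                  now_remitted=m.edema_resolved,
                                  epsilon_pct=cfg.direction_epsilon_pct)
            label = congruence(
                core_dir, edema_dir,
                unchanged_congruent=cfg.unchanged_pairs_congruent)
            cong = label.value if label is not None else None
            if (cur_edema is not None and baseline_edema
                    and baseline_edema > 0
                    and not (series.is_new_lesion
                             and m.days_from_srt == series.appearance_day)):
                rel_edema = 100.0 * cur_edema / baseline_edema
            if cur_edema is not None:
                prev_edema = cur_edema

        out.windows.append(ResponseAssessment(
            window=w.label, days_from_srt=m.days_from_srt, rano=rano,
            edema_grade=grade, core_direction=core_dir,
            edema_direction=edema_dir, congruence=cong,
            relative_ld_pct=rel_ld, relative_edema_pct=rel_edema))

        if first_labelled and cong is not None:
            out.incongruent_at_first_followup = cong == "incongruent"
            first_labelled = False
        if m.ld_mm is not None:
            prev_ld = m.ld_mm
        elif not m.core_present:
            prev_ld = 0.0
        seen_any_scan = True

    # trajectory patterns over every follow-up scan (not window-selected)
    if baseline_ld and baseline_ld > 0:
        core_vals = [100.0]
        for m in series.followups():
            if m.ld_mm is not None:
                core_vals.append(100.0 * m.ld_mm / baseline_ld)
            elif not m.core_present:
                core_vals.append(0.0)
        out.core_pattern = pattern_label(core_vals)
    if include_edema and baseline_edema and baseline_edema > 0:
        edema_vals = [100.0]
        for m in series.followups():
            v = _edema_value(m)
            if v is not None:
                edema_vals.append(100.0 * v / baseline_edema)
        out.edema_pattern = pattern_label(edema_vals)
    return out
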