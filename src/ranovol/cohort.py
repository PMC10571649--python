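"""Longitudinal cohort model: lesions, timepoints, baselines, windows.

One row of the long-format cohort table is a lesion at a timepoint.
Days are counted from the day of stereotactic radiotherapy (SRT);
negative days are pre-treatment.  The tumor-core baseline is the
SRT-day (day 0) scan; the edema baseline is the latest scan in the 30
days before treatment (FLAIR is not acquired on the treatment day
itself).  Follow-up scans are binned into right-closed windows
(0,90], (90,180], (180,270], (270,365], (365,inf) days.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMA_COLUMNS",
    "LesionMeasurement",
    "LesionSeries",
    "FollowUpWindow",
    "followup_windows",
    "assign_window",
    "select_window_measurement",
    "relative_size",
    "nadir_ld",
    "apply_exclusions",
    "ExclusionResult",
    "build_series",
    "read_cohort_csv",
    "write_cohort_csv",
    "validate_cohort_table",
]

#: exact column order of the long-format cohort CSV; empty cell = absent
SCHEMA_COLUMNS = [
    "patient_id", "lesion_id", "days_from_srt", "ld_mm", "perp_mm",
    "edema_cm3", "core_present", "edema_resolved", "confluent_edema",
    "on_steroids", "slice_thickness_mm", "flair_available", "histology",
]

_BOOL_COLUMNS = ["core_present", "edema_resolved", "confluent_edema",
                 "on_steroids", "flair_available"]

DEFAULT_WINDOW_EDGES = (0, 90, 180, 270, 365)


@dataclass(frozen=True)
class FollowUpWindow:
    """Half-open follow-up window (start_day, end_day] post-SRT; end_day
    None means unbounded."""

    label: str
    start_day: int
    end_day: Optional[int]

    def contains(self, days: int) -> bool:
        if days <= self.start_day:
            return False
        return self.end_day is None or days <= self.end_day


def followup_windows(edges: Sequence[int] = DEFAULT_WINDOW_EDGES
                     ) -> Tuple[FollowUpWindow, ...]:
    """Windows (e0,e1], (e1,e2], ..., (e_last, inf) labelled W1..Wk."""
    edges = list(edges)
    wins = []
    for i in range(len(edges) - 1):
        wins.append(FollowUpWindow(f"W{i + 1}", edges[i], edges[i + 1]))
    wins.append(FollowUpWindow(f"W{len(edges)}", edges[-1], None))
    return tuple(wins)


def assign_window(days_from_srt: int,
                  edges: Sequence[int] = DEFAULT_WINDOW_EDGES) -> FollowUpWindow:
    """The unique follow-up window containing a positive day count.

    Raises ``ValueError`` for days <= 0 (baseline or pre-SRT scans are
    not follow-up).
    """
    if days_from_srt <= 0:
        raise ValueError(
            f"day {days_from_srt}: baseline/pre-SRT, not a follow-up")
    for w in followup_windows(edges):
        if w.contains(days_from_srt):
            return w
    raise AssertionError("windows are exhaustive for positive days")


@dataclass
class LesionMeasurement:
    """One lesion at one timepoint.  ``None`` marks an absent value."""

    patient_id: str
    lesion_id: str
    days_from_srt: int
    ld_mm: Optional[float] = None
    perp_mm: Optional[float] = None
    edema_cm3: Optional[float] = None
    core_present: bool = True
    edema_resolved: bool = False
    confluent_edema: bool = False
    on_steroids: bool = False

    def __post_init__(self) -> None:
        if not self.core_present and self.ld_mm is not None:
            raise ValueError("core_present=False requires ld_mm absent")
        if self.edema_resolved and self.edema_cm3 not in (None, 0, 0.0):
            raise ValueError("edema_resolved=True requires edema 0 or absent")
        for name in ("ld_mm", "perp_mm", "edema_cm3"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class LesionSeries:
    """Time-ordered measurements for one lesion plus its baselines.

    ``baseline_ld_mm`` comes from the day-0 scan; ``baseline_edema_cm3``
    from the latest scan in [-30, 0] days with an edema value.  Lesions
    with no scan at or before day 0 are new lesions: their first
    appearance becomes the baseline for subsequent relative metrics and
    they never contribute a relative value at the appearance timepoint.
    """

    patient_id: str
    lesion_id: str
    measurements: List[LesionMeasurement] = field(default_factory=list)
    baseline_ld_mm: Optional[float] = None
    baseline_perp_mm: Optional[float] = None
    baseline_edema_cm3: Optional[float] = None
    is_new_lesion: bool = False
    appearance_day: Optional[int] = None
    confluent_edema: bool = False
    slice_thickness_mm: Optional[float] = None
    flair_available: bool = True
    histology: Optional[str] = None

    def followups(self) -> List[LesionMeasurement]:
        """Measurements strictly after day 0 (after appearance, for new
        lesions)."""
        start = self.appearance_day if self.is_new_lesion else 0
        return [m for m in self.measurements if m.days_from_srt > start]


def select_window_measurement(series: LesionSeries, window: FollowUpWindow
                              ) -> Optional[LesionMeasurement]:
    """Earliest measurement falling in the window, or None."""
    hits = [m for m in series.followups() if window.contains(m.days_from_srt)]
    if not hits:
        return None
    return min(hits, key=lambda m: m.days_from_srt)


def relative_size(current: float, baseline: float) -> float:
    """Size relative to baseline, in percent (100 x current / baseline)."""
    if baseline is None or baseline <= 0:
        raise ValueError("relative size undefined for baseline <= 0")
    return 100.0 * current / baseline


def nadir_ld(series: LesionSeries, up_to_day: int, *,
             post_cr_zero: bool = False) -> Optional[float]:
    """Smallest LD recorded at or before ``up_to_day``.

    The minimum runs over the baseline LD and every follow-up LD with
    days_from_srt <= up_to_day.  Scans without an LD are skipped, unless
    ``post_cr_zero`` is set, in which case a complete-response scan
    (core absent) pulls the nadir to 0 so that any reappearance counts
    as progression.
    """
    values = []
    if series.baseline_ld_mm is not None:
        values.append(series.baseline_ld_mm)
    for m in series.followups():
        if m.days_from_srt > up_to_day:
            continue
        if m.ld_mm is not None:
            values.append(m.ld_mm)
        elif post_cr_zero and not m.core_present:
            values.append(0.0)
    if not values:
        return None
    return float(min(values))


def _row_val(row, col):
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def build_series(df: pd.DataFrame) -> List[LesionSeries]:
    """Assemble one ``LesionSeries`` per (patient, lesion) from the long
    table, deriving baselines and new-lesion flags."""
    out: List[LesionSeries] = []
    for (pid, lid), grp in df.groupby(["patient_id", "lesion_id"], sort=True):
        grp = grp.sort_values("days_from_srt")
        meas = []
        for _, row in grp.iterrows():
            meas.append(LesionMeasurement(
                patient_id=str(pid), lesion_id=str(lid),
                days_from_srt=int(row["days_from_srt"]),
                ld_mm=_row_val(row, "ld_mm"),
                perp_mm=_row_val(row, "perp_mm"),
                edema_cm3=_row_val(row, "edema_cm3"),
                core_present=bool(row["core_present"]),
                edema_resolved=bool(row["edema_resolved"]),
                confluent_edema=bool(row["confluent_edema"]),
                on_steroids=bool(row["on_steroids"]),
            ))
        s = LesionSeries(
            patient_id=str(pid), lesion_id=str(lid), measurements=meas,
            confluent_edema=any(m.confluent_edema for m in meas),
            slice_thickness_mm=_row_val(grp.iloc[0], "slice_thickness_mm"),
            flair_available=bool(grp.iloc[0]["flair_available"]),
            histology=str(grp.iloc[0]["histology"]),
        )
        pre = [m for m in meas if m.days_from_srt <= 0]
        if pre:
            day0 = [m for m in pre if m.days_from_srt == 0]
            if day0:
                s.baseline_ld_mm = day0[0].ld_mm
                s.baseline_perp_mm = day0[0].perp_mm
            # edema baseline: latest scan in [-30, 0] carrying an edema value
            cands = [m for m in pre
                     if m.days_from_srt >= -30 and m.edema_cm3 is not None]
            if cands:
                s.baseline_edema_cm3 = max(
                    cands, key=lambda m: m.days_from_srt).edema_cm3
        else:
            s.is_new_lesion = True
            first = meas[0]
            s.appearance_day = first.days_from_srt
            s.baseline_ld_mm = first.ld_mm
            s.baseline_perp_mm = first.perp_mm
            s.baseline_edema_cm3 = first.edema_cm3
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# exclusions

#: exclusion rules, ordered; first matching rule wins
_RULES = [
    ("3_slice_or_flair",
     lambda s: (s.slice_thickness_mm is not None and s.slice_thickness_mm >= 3.0)
     or not s.flair_available),
    ("4_histology", lambda s: (s.histology or "NSCLC") != "NSCLC"),
    ("5_baseline_ld", lambda s: s.baseline_ld_mm is None
     or s.baseline_ld_mm < 10.0),
]


@dataclass
class ExclusionResult:
    """Cohort after eligibility filtering.

    ``ld_series`` are lesions retained for 2-D diameter analyses;
    ``edema_series`` additionally drops lesions with confluent
    peritumoral edema (their edema cannot be assigned to one core).
    ``log`` records one row per removed or restricted lesion with the
    id of the first matching rule.
    """

    ld_series: List[LesionSeries]
    edema_series: List[LesionSeries]
    log: pd.DataFrame


def apply_exclusions(series_list: Sequence[LesionSeries]) -> ExclusionResult:
    """Apply the eligibility rules lesion by lesion.

    Rules, in order: (3) slice thickness >= 3 mm or FLAIR missing;
    (4) histology other than NSCLC; (5) baseline LD < 10 mm.  New
    lesions are exempt from rule 5 (they have no treatment-day scan to
    judge).  Lesions with confluent edema stay in the LD analyses but
    leave the edema-volume analyses; that restriction is logged with its
    own rule id.  Idempotent: re-applying to the retained set removes
    nothing.
    """
    ld_keep, edema_keep, log_rows = [], [], []
    for s in series_list:
        rule = None
        for rid, pred in _RULES:
            if rid == "5_baseline_ld" and s.is_new_lesion:
                continue
            if pred(s):
                rule = rid
                break
        if rule is not None:
            log_rows.append({"patient_id": s.patient_id,
                             "lesion_id": s.lesion_id, "rule": rule,
                             "scope": "all"})
            continue
        ld_keep.append(s)
        if s.confluent_edema:
            log_rows.append({"patient_id": s.patient_id,
                             "lesion_id": s.lesion_id,
                             "rule": "confluent_edema",
                             "scope": "edema_only"})
        else:
            edema_keep.append(s)
    log = pd.DataFrame(log_rows,
                       columns=["patient_id", "lesion_id", "rule", "scope"])
    return ExclusionResult(ld_series=ld_keep, edema_series=edema_keep, log=log)


# ---------------------------------------------------------------------------
# I/O

def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the long-format cohort table with the exact schema column
    order; absent values become empty cells."""
    out = df.reindex(columns=SCHEMA_COLUMNS)
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort CSV, coercing types and validating the schema."""
    df = pd.read_csv(path)
    errors = validate_cohort_table(df)
    if errors:
        raise ValueError("invalid cohort table:\n" + "\n".join(errors))
    for col in _BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    df["days_from_srt"] = df["days_from_srt"].astype(int)
    df["patient_id"] = df["patient_id"].astype(str)
    df["lesion_id"] = df["lesion_id"].astype(str)
    return df


def validate_cohort_table(df: pd.DataFrame) -> List[str]:
    """Schema checks; returns human-readable errors with 1-based data
    row numbers (empty list = valid)."""
    errors = []
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {', '.join(missing)}"]
    if df["days_from_srt"].isna().any():
        rows = df.index[df["days_from_srt"].isna()].tolist()
        errors.append(f"rows {rows}: days_from_srt is required")
    for col in ("ld_mm", "perp_mm", "edema_cm3"):
        bad = df.index[df[col].notna() & (df[col] < 0)]
        for i in bad:
            errors.append(f"row {i + 1}: {col} negative ({df.at[i, col]})")
    bad = df.index[(~df["core_present"].astype(bool)) & df["ld_mm"].notna()]
    for i in bad:
        errors.append(f"row {i + 1}: ld_mm present but core_present is false")
    bad = df.index[df["edema_resolved"].astype(bool) & df["edema_cm3"].notna()
                   & (df["edema_cm3"] != 0)]
    for i in bad:
        errors.append(f"row {i + 1}: edema_resolved but edema_cm3 nonzero")
    return errors


def series_to_json(series_list: Sequence[LesionSeries],
                   edges: Sequence[int] = DEFAULT_WINDOW_EDGES) -> str:
    """JSON export of assembled series with baselines and window labels."""
    payload = []
    for s in series_list:
        rows = []
        for m in s.followups():
            rows.append({
                "days_from_srt": m.days_from_srt,
                "window": assign_window(m.days_from_srt, edges).label,
                "ld_mm": m.ld_mm, "perp_mm": m.perp_mm,
                "edema_cm3": m.edema_cm3,
                "core_present": m.core_present,
                "edema_resolved": m.edema_resolved,
            })
        payload.append({
            "patient_id": s.patient_id, "lesion_id": s.lesion_id,
            "baseline_ld_mm": s.baseline_ld_mm,
            "baseline_edema_cm3": s.baseline_edema_cm3,
            "is_new_lesion": s.is_new_lesion,
            "confluent_edema": s.confluent_edema,
            "followups": rows,
        })
    return json.dumps(payload, indent=2)
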