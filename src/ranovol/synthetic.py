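"""Synthetic inputs: voxel phantoms and simulated longitudinal cohorts.

The phantom generator digitises spheres/ellipsoids onto a voxel grid so
the geometry code can be validated against analytic volumes and
diameters.  The cohort simulator emulates the structure of a
stereotactic-radiotherapy brain-metastasis cohort: lesions per patient
(median 4, IQR 3-10), baseline longest diameter (median 14 mm, IQR
11-17), baseline peritumoral edema volume (median 8.1 cm^3, IQR
0.8-50), 1-7 follow-up scans at 6-12-week intervals with dropout such
that about half the patients end before the seventh follow-up, and a
mixture of edema trajectory patterns (continuous decrease, waxing and
waning, paradoxical early increase, complete remission, continuous
increase).  Core-LD trajectories are coupled to edema trajectories in
log space with an elasticity < 1 (edema swings harder than the core),
with a configurable probability of an incongruent first follow-up.

Every lesion carries hidden ground truth (its generating pattern and
the per-window congruence labels computed from the noiseless values),
so the downstream classifiers can be scored without any real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import SCHEMA_COLUMNS, assign_window, write_cohort_csv
from .mask_geometry import LabeledMaskVolume
from .response import PatternLabel

__all__ = [
    "PhantomSpec", "generate_phantom", "SyntheticCohort", "simulate_cohort",
    "cohort_calibration_report", "DEFAULT_MIXTURE",
]

# quartiles of the standard normal: IQR of a lognormal spans
# exp(mu -/+ 0.6745 sigma)
_Z_IQR = 2 * 0.674489750196082


def _lognormal_from_median_iqr(median: float, q1: float, q3: float
                               ) -> Tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR."""
    return math.log(median), math.log(q3 / q1) / _Z_IQR


# ---------------------------------------------------------------------------
# phantoms

@dataclass(frozen=True)
class PhantomSpec:
    """Geometric core + edema phantom on a voxel grid.

    Semi-axes and the centre are in mm; a sphere is an ellipsoid with
    equal semi-axes.  The edema envelope must contain the core
    componentwise, matching the convention that the segmented edema
    includes the tumor core.
    """

    core_semi_axes_mm: Tuple[float, float, float]
    edema_semi_axes_mm: Tuple[float, float, float]
    center_mm: Tuple[float, float, float]
    spacing: Tuple[float, float, float]
    grid_shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(e < c for c, e in zip(self.core_semi_axes_mm,
                                     self.edema_semi_axes_mm)):
            raise ValueError("edema semi-axes must cover the core "
                             "componentwise")
        if any(a <= 0 for a in self.core_semi_axes_mm):
            raise ValueError("semi-axes must be strictly positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    def analytic_volume_cm3(self, which: str = "core") -> float:
        axes = (self.core_semi_axes_mm if which == "core"
                else self.edema_semi_axes_mm)
        a, b, c = axes
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def _ellipsoid_mask(semi, center, spacing, grid_shape) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    terms = []
    for ax, (c, a) in enumerate(zip(center, semi)):
        t = ((coords[ax] - c) / a) ** 2
        shape = [1, 1, 1]
        shape[ax] = -1
        terms.append(t.reshape(shape))
    return (terms[0] + terms[1] + terms[2] <= 1.0).astype(np.uint8)


def generate_phantom(spec: PhantomSpec
                     ) -> Tuple[LabeledMaskVolume, LabeledMaskVolume]:
    """Digitise the phantom: a voxel belongs to a mask iff its centre
    lies inside (or on) the analytic surface.  The edema mask is the
    union of the edema ellipsoid with the core.  Raises if either
    surface extends beyond the range of voxel centres (clipping would
    silently bias volumes)."""
    for semi in (spec.core_semi_axes_mm, spec.edema_semi_axes_mm):
        for ax in range(3):
            lo = spec.center_mm[ax] - semi[ax]
            hi = spec.center_mm[ax] + semi[ax]
            extent = (spec.grid_shape[ax] - 1) * spec.spacing[ax]
            if lo < 0 or hi > extent:
                raise ValueError("phantom clipped by grid boundary on "
                                 f"axis {ax}")
    core = _ellipsoid_mask(spec.core_semi_axes_mm, spec.center_mm,
                           spec.spacing, spec.grid_shape)
    edema = _ellipsoid_mask(spec.edema_semi_axes_mm, spec.center_mm,
                            spec.spacing, spec.grid_shape)
    edema |= core
    return (LabeledMaskVolume(core, spec.spacing, "core"),
            LabeledMaskVolume(edema, spec.spacing, "edema"))


# ---------------------------------------------------------------------------
# cohort simulation

#: edema-trajectory pattern mixture: of 31 followed lesions, 24 decreased
#: (11 continuously, 6 waxing-waning, 4 with a paradoxical early increase,
#: 3 to complete remission) and 7 increased
DEFAULT_MIXTURE: Dict[PatternLabel, float] = {
    PatternLabel.CONTINUOUS_DECREASE: 11 / 31,
    PatternLabel.WAXING_WANING: 6 / 31,
    PatternLabel.PARADOXICAL_THEN_DECREASE: 4 / 31,
    PatternLabel.COMPLETE_REMISSION: 3 / 31,
    PatternLabel.CONTINUOUS_INCREASE: 7 / 31,
}

#: per-window probability that a patient is on steroids in that window
_STEROID_WINDOW_P = (0.50, 0.41, 0.18, 0.30, 0.0)
_STEROID_PERI_SRT_P = 0.65

_PATTERN_MIN_FOLLOWUPS = {
    PatternLabel.CONTINUOUS_DECREASE: 2,
    PatternLabel.CONTINUOUS_INCREASE: 2,
    PatternLabel.COMPLETE_REMISSION: 2,
    PatternLabel.PARADOXICAL_THEN_DECREASE: 2,
    PatternLabel.WAXING_WANING: 3,
}


@dataclass
class SyntheticCohort:
    """Simulated measurement table plus hidden ground truth.

    ``table`` follows the cohort CSV schema.  ``truth_patterns`` has one
    row per lesion (generating edema pattern, flags);
    ``truth_congruence`` one row per lesion-window with the congruence
    label implied by the noiseless trajectories.  Truth keys match the
    measurement table keys one-to-one.
    """

    table: pd.DataFrame
    truth_patterns: pd.DataFrame
    truth_congruence: pd.DataFrame
    params: dict = field(default_factory=dict)
    seed: int = 0

    def write(self, outdir) -> None:
        import pathlib
        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort_csv(self.table, out / "cohort.csv")
        truth = {
            "seed": self.seed,
            "params": self.params,
            "patterns": self.truth_patterns.to_dict(orient="records"),
            "congruence": self.truth_congruence.to_dict(orient="records"),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def _edema_trajectory(pattern: PatternLabel, n_fu: int, rng
                      ) -> Tuple[List[float], List[bool]]:
    """Noiseless relative edema values (percent of baseline) per
    follow-up scan, plus a per-scan resolved flag."""
    vals: List[float] = []
    resolved = [False] * n_fu
    if pattern is PatternLabel.CONTINUOUS_DECREASE:
        v = 100.0
        for _ in range(n_fu):
            v *= rng.uniform(0.25, 0.80)
            vals.append(v)
    elif pattern is PatternLabel.CONTINUOUS_INCREASE:
        v = 100.0
        for _ in range(n_fu):
            v *= rng.uniform(1.20, 2.60)
            vals.append(v)
    elif pattern is PatternLabel.COMPLETE_REMISSION:
        r = int(rng.integers(2, n_fu + 1)) if n_fu >= 2 else n_fu
        v = 100.0
        for k in range(1, n_fu + 1):
            if k >= r:
                vals.append(0.0)
                resolved[k - 1] = True
            else:
                v *= rng.uniform(0.25, 0.70)
                vals.append(v)
    elif pattern is PatternLabel.PARADOXICAL_THEN_DECREASE:
        v = 100.0 * rng.uniform(1.20, 1.70)
        vals.append(v)
        for _ in range(n_fu - 1):
            v *= rng.uniform(0.30, 0.75)
            vals.append(v)
    elif pattern is PatternLabel.WAXING_WANING:
        # regrow at the second or third follow-up, never above baseline
        u = 2 if (n_fu < 4 or rng.random() < 0.5) else 3
        u = min(u, n_fu - 1)
        v = 100.0
        for k in range(1, n_fu + 1):
            if k == u:
                v = min(v * rng.uniform(1.40, 1.90), 85.0)
            else:
                v *= rng.uniform(0.30, 0.60)
            vals.append(v)
    else:
        raise ValueError(f"no trajectory template for pattern {pattern}")
    return vals, resolved


def _core_trajectory(edema_rel: List[float], resolved: List[bool],
                     rng, *, incongruence_w1: float, follow_p: float,
                     elasticity: float) -> List[float]:
    """Relative core-LD values coupled to the edema trajectory.

    Per scan, the core moves in the edema's direction (opposite at the
    first scan with probability ``incongruence_w1``, and with
    probability 1 - ``follow_p`` later) with a log-magnitude equal to
    ``elasticity`` times the edema's."""
    core = []
    v = 100.0
    prev_e = 100.0
    for k, e in enumerate(edema_rel):
        e_eff = e if e > 0 else prev_e * 0.3  # remission: strong decrease
        log_ratio = math.log(max(e_eff, 1e-6) / max(prev_e, 1e-6))
        if log_ratio == 0.0:
            log_ratio = -1e-3
        if k == 0:
            same = rng.random() >= incongruence_w1
        else:
            same = rng.random() < follow_p
        sign = 1.0 if (log_ratio > 0) == same else -1.0
        v *= math.exp(sign * max(abs(log_ratio) * elasticity, 0.02))
        core.append(v)
        prev_e = e_eff if e > 0 else prev_e
    return core


def _sign_direction(prev: float, cur: float, cur_remitted: bool) -> str:
    if cur_remitted:
        return "remitted"
    if prev == 0:
        return "increasing" if cur > 0 else "remitted"
    if cur > prev:
        return "increasing"
    if cur < prev:
        return "decreasing"
    return "unchanged"


def _noise_factor(rng, sigma: float) -> float:
    return math.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0


def simulate_cohort(n_patients: int,
                    mixture: Optional[Dict[PatternLabel, float]] = None,
                    seed: int = 0, *,
                    noise_cv: float = 0.05,
                    dropout_hazard: float = 0.109,
                    incongruence_w1: float = 0.32,
                    follow_p: float = 0.80,
                    elasticity: float = 0.5,
                    p_confluent: float = 0.18,
                    p_new_lesion: float = 0.08,
                    p_core_cr: float = 0.30,
                    baseline_ld: Tuple[float, float, float] = (14.0, 11.0, 17.0),
                    baseline_edema: Tuple[float, float, float] = (8.1, 0.8, 50.0),
                    baseline_correlation: float = 0.75,
                    lesions_per_patient: Tuple[float, float, float] = (4.0, 3.0, 10.0),
                    ) -> SyntheticCohort:
    """Simulate a longitudinal cohort with ground-truth labels.

    Parameters
    ----------
    n_patients : int
        Number of patients; each carries a log-normal number of lesions
        (median 4, IQR 3-10 by default).
    mixture : dict, optional
        Edema-pattern proportions; must sum to 1.  Defaults to the
        observed 11/6/4/3/7 (of 31) mixture.
    seed : int
        Single source of randomness; identical seed and parameters give
        byte-identical tables.
    noise_cv : float
        Coefficient of variation of multiplicative log-normal
        measurement noise applied to every recorded LD and edema value.
    dropout_hazard : float
        Per-interval probability that a patient's follow-up ends; the
        default 0.109 makes about half of patients stop before the
        seventh follow-up.
    incongruence_w1 : float
        Probability that the core moves opposite to the edema at the
        first follow-up scan.
    follow_p : float
        Probability that the core follows the edema's direction at
        later scans.
    elasticity : float
        Ratio of core to edema log-change magnitude (< 1: edema swings
        harder).

    Returns
    -------
    SyntheticCohort
        Measurement table (cohort CSV schema), per-lesion pattern truth
        and per-lesion-window congruence truth.
    """
    mixture = dict(DEFAULT_MIXTURE) if mixture is None else dict(mixture)
    bad = [k for k in mixture if not isinstance(k, PatternLabel)]
    if bad or abs(sum(mixture.values()) - 1.0) > 1e-9 \
            or any(v < 0 for v in mixture.values()):
        raise ValueError("mixture must map PatternLabel to nonnegative "
                         "proportions summing to 1")
    patterns = list(mixture.keys())
    probs = np.array([mixture[p] for p in patterns], dtype=float)

    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0
    mu_ld, sd_ld = _lognormal_from_median_iqr(*baseline_ld)
    mu_ed, sd_ed = _lognormal_from_median_iqr(*baseline_edema)
    mu_les, sd_les = _lognormal_from_median_iqr(*lesions_per_patient)

    rows: List[dict] = []
    truth_pat: List[dict] = []
    truth_cong: List[dict] = []

    for i in range(n_patients):
        pid = f"P{i:04d}"
        n_fu = 1
        while n_fu < 7 and rng.random() >= dropout_hazard:
            n_fu += 1
        scan_days = np.cumsum(rng.integers(42, 85, size=n_fu)).tolist()
        steroid_w = [rng.random() < p for p in _STEROID_WINDOW_P]
        steroid_base = rng.random() < _STEROID_PERI_SRT_P
        slice_mm = 3.0 if rng.random() < 0.05 else 1.0
        flair = rng.random() >= 0.03
        histology = "NSCLC" if rng.random() >= 0.05 else "other"
        n_lesions = max(1, int(round(rng.lognormal(mu_les, sd_les))))
        has_new = rng.random() < p_new_lesion and n_fu >= 4

        def window_index(day: int) -> int:
            return int(assign_window(day).label[1:]) - 1

        def steroid_at(day: int) -> bool:
            if day <= 0:
                return steroid_base
            return steroid_w[window_index(day)]

        for j in range(n_lesions + int(has_new)):
            lid = f"{pid}-L{j:02d}"
            is_new = has_new and j == n_lesions
            pattern = (PatternLabel.CONTINUOUS_INCREASE if is_new
                       else patterns[int(rng.choice(len(patterns), p=probs))])
            # Gaussian copula couples baseline edema to baseline LD
            # (bigger cores carry more edema) while preserving both
            # log-normal marginals
            z1 = rng.standard_normal()
            z2 = (baseline_correlation * z1
                  + math.sqrt(1 - baseline_correlation ** 2)
                  * rng.standard_normal())
            base_ld = float(math.exp(mu_ld + sd_ld * z1))
            base_edema = float(math.exp(mu_ed + sd_ed * z2))
            confluent = (not is_new) and rng.random() < p_confluent

            if is_new:
                appear = 2  # appears at the second follow-up scan
                lesion_days = scan_days[appear - 1:]
                n_scans = len(lesion_days)
            else:
                lesion_days = scan_days
                n_scans = n_fu

            edema_rel, resolved = _edema_trajectory(pattern, n_scans, rng)
            core_rel = _core_trajectory(
                edema_rel, resolved, rng, incongruence_w1=incongruence_w1,
                follow_p=follow_p, elasticity=elasticity)
            core_cr_from = None
            if (pattern is PatternLabel.COMPLETE_REMISSION
                    and rng.random() < p_core_cr):
                core_cr_from = resolved.index(True)

            perp_frac = rng.uniform(0.55, 0.95, size=n_scans + 1)

            # baseline rows
            if not is_new:
                pre_day = -int(rng.integers(1, 31))
                rows.append({
                    "patient_id": pid, "lesion_id": lid,
                    "days_from_srt": pre_day, "ld_mm": None, "perp_mm": None,
                    "edema_cm3": base_edema * _noise_factor(rng, sigma),
                    "core_present": True, "edema_resolved": False,
                    "confluent_edema": confluent,
                    "on_steroids": steroid_at(pre_day),
                    "slice_thickness_mm": slice_mm, "flair_available": flair,
                    "histology": histology})
                ld0 = base_ld * _noise_factor(rng, sigma)
                rows.append({
                    "patient_id": pid, "lesion_id": lid, "days_from_srt": 0,
                    "ld_mm": ld0, "perp_mm": ld0 * perp_frac[0],
                    "edema_cm3": None, "core_present": True,
                    "edema_resolved": False, "confluent_edema": confluent,
                    "on_steroids": steroid_at(0),
                    "slice_thickness_mm": slice_mm, "flair_available": flair,
                    "histology": histology})

            # follow-up rows (for new lesions the first row IS the baseline)
            true_ld = [base_ld * r / 100.0 for r in core_rel]
            true_edema = [base_edema * r / 100.0 for r in edema_rel]
            if is_new:
                # appearance scan carries baseline values
                true_ld = [base_ld] + true_ld[:-1]
                true_edema = [base_edema] + true_edema[:-1]
                resolved = [False] + resolved[:-1]

            for k, day in enumerate(lesion_days):
                cr = core_cr_from is not None and k >= core_cr_from
                ld_val = (None if cr
                          else true_ld[k] * _noise_factor(rng, sigma))
                ed_val = (0.0 if resolved[k]
                          else true_edema[k] * _noise_factor(rng, sigma))
                rows.append({
                    "patient_id": pid, "lesion_id": lid,
                    "days_from_srt": int(day), "ld_mm": ld_val,
                    "perp_mm": (None if ld_val is None
                                else ld_val * perp_frac[k + 1]),
                    "edema_cm3": ed_val, "core_present": not cr,
                    "edema_resolved": bool(resolved[k]),
                    "confluent_edema": confluent,
                    "on_steroids": steroid_at(int(day)),
                    "slice_thickness_mm": slice_mm, "flair_available": flair,
                    "histology": histology})

            truth_pat.append({
                "patient_id": pid, "lesion_id": lid,
                "pattern": pattern.value, "is_new_lesion": is_new,
                "confluent_edema": confluent, "n_followups": n_scans,
                "died_before_seventh": n_fu < 7})

            # noiseless per-window congruence truth (earliest scan per
            # window; the appearance scan of a new lesion is its baseline,
            # not a follow-up, so it is skipped entirely)
            selected: Dict[str, int] = {}
            for k, day in enumerate(lesion_days):
                if is_new and k == 0:
                    continue
                w = assign_window(int(day)).label
                if w not in selected:
                    selected[w] = k
            prev_ld_t, prev_ed_t = base_ld, base_edema
            for w in sorted(selected, key=lambda s: int(s[1:])):
                k = selected[w]
                cr = core_cr_from is not None and k >= core_cr_from
                cur_ld = 0.0 if cr else true_ld[k]
                cur_ed = 0.0 if resolved[k] else true_edema[k]
                cdir = _sign_direction(prev_ld_t, cur_ld, cr)
                edir = _sign_direction(prev_ed_t, cur_ed, bool(resolved[k]))
                ok = (cdir == edir
                      and cdir in ("increasing", "decreasing", "remitted"))
                truth_cong.append({
                    "patient_id": pid, "lesion_id": lid, "window": w,
                    "congruence": "congruent" if ok else "incongruent",
                    "core_direction": cdir, "edema_direction": edir})
                prev_ld_t, prev_ed_t = cur_ld, cur_ed

    table = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    params = {
        "n_patients": n_patients, "noise_cv": noise_cv,
        "dropout_hazard": dropout_hazard,
        "incongruence_w1": incongruence_w1, "follow_p": follow_p,
        "elasticity": elasticity, "p_confluent": p_confluent,
        "p_new_lesion": p_new_lesion, "p_core_cr": p_core_cr,
        "baseline_correlation": baseline_correlation,
        "baseline_ld": list(baseline_ld),
        "baseline_edema": list(baseline_edema),
        "lesions_per_patient": list(lesions_per_patient),
        "mixture": {k.value: v for k, v in mixture.items()},
    }
    return SyntheticCohort(
        table=table,
        truth_patterns=pd.DataFrame(
            truth_pat, columns=["patient_id", "lesion_id", "pattern",
                                "is_new_lesion", "confluent_edema",
                                "n_followups", "died_before_seventh"]),
        truth_congruence=pd.DataFrame(
            truth_cong, columns=["patient_id", "lesion_id", "window",
                                 "congruence", "core_direction",
                                 "edema_direction"]),
        params=params, seed=seed)


def cohort_calibration_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Medians and IQRs of the simulated cohort against its calibration
    constants.

    One row per calibrated variable (lesions per patient, baseline LD,
    baseline edema volume) with the realised n / median / IQR and the
    target median the generator was asked for.  A degenerate
    (single-pattern) mixture is flagged in the ``note`` column.
    """
    df = cohort.table
    if df.empty:
        raise ValueError("calibration report undefined for an empty cohort")
    per_patient = df.groupby("patient_id")["lesion_id"].nunique()
    base_ld = df.loc[df["days_from_srt"] == 0, "ld_mm"].dropna()
    base_ed = df.loc[df["days_from_srt"] < 0, "edema_cm3"].dropna()

    mix = cohort.params.get("mixture", {})
    active = [k for k, v in mix.items() if v > 0]
    note = "single-pattern cohort" if len(active) == 1 else ""

    def row(name, values, target):
        q1, med, q3 = np.percentile(np.asarray(values, dtype=float),
                                    [25, 50, 75])
        return {"variable": name, "n": len(values), "median": med,
                "q1": q1, "q3": q3, "target_median": target[0],
                "target_q1": target[1], "target_q3": target[2],
                "note": note}

    return pd.DataFrame([
        row("lesions_per_patient", per_patient,
            cohort.params["lesions_per_patient"]),
        row("baseline_ld_mm", base_ld, cohort.params["baseline_ld"]),
        row("baseline_edema_cm3", base_ed, cohort.params["baseline_edema"]),
    ])
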