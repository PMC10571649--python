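"""Analysis configuration: every classification threshold in one place.

All thresholds default to the RANO-BM / edema-grading conventions used
throughout the package (partial response at a 30 % LD decrease from
baseline, progression at a 20 % increase from nadir, measurability at
10 mm LD with a 5 mm perpendicular, a ±25 % stability band for edema
volume).  Sensitivity analyses change a field here, nothing else.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    """Thresholds and conventions for response assessment.

    Parameters
    ----------
    pr_pct : float
        Partial response: decrease in longest diameter (LD) from baseline,
        in percent, at or above which a lesion is PR.  Inclusive.
    pd_pct : float
        Progressive disease: increase in LD from nadir, in percent, at or
        above which a lesion is PD.  Inclusive.
    edema_band_pct : float
        Half-width of the "stable" edema-volume band in percent change
        from baseline; the band is open (strictly less than) so the
        boundary belongs to the directional grade.
    measurable_ld_mm, measurable_perp_mm : float
        Minimum LD and perpendicular diameter (mm, inclusive) for a
        lesion to count as measurable.
    direction_epsilon_pct : float
        Relative change (percent) below which a quantity is "unchanged"
        when labelling trajectory direction.  0 means any change counts.
    unchanged_pairs_congruent : bool
        Whether a (unchanged, unchanged) direction pair is congruent.
        The strict reading is False.
    window_edges_days : tuple of int
        Right-closed follow-up window edges in days post-treatment:
        (0, 90, 180, 270, 365) gives (0,90], (90,180], (180,270],
        (270,365], (365, inf).
    max_target_lesions : int
        Cap on the number of target lesions summed into the patient-level
        sum of LD.
    """

    pr_pct: float = 30.0
    pd_pct: float = 20.0
    edema_band_pct: float = 25.0
    measurable_ld_mm: float = 10.0
    measurable_perp_mm: float = 5.0
    direction_epsilon_pct: float = 0.0
    unchanged_pairs_congruent: bool = False
    window_edges_days: tuple = (0, 90, 180, 270, 365)
    max_target_lesions: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("pr_pct", "pd_pct", "edema_band_pct",
                     "measurable_ld_mm", "measurable_perp_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.direction_epsilon_pct < 0:
            raise ValueError("direction_epsilon_pct must be nonnegative")
        self.window_edges_days = tuple(int(e) for e in self.window_edges_days)
        if list(self.window_edges_days) != sorted(set(self.window_edges_days)):
            raise ValueError("window_edges_days must be strictly increasing")
        if self.max_target_lesions < 1:
            raise ValueError("max_target_lesions must be at least 1")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisConfig":
        return cls(**json.loads(text))

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_json(fh.read())
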