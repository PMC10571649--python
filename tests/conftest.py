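import numpy as np
import pytest

from ranovol import LesionMeasurement, LesionSeries


def make_series(baseline_ld=14.0, baseline_edema=10.0, scans=(),
                patient="P1", lesion="L1", **series_kw):
    """LesionSeries from (day, ld_mm, edema_cm3) triples.

    ld None with core present is skipped-LD; ld "CR" marks a vanished
    core; edema 0.0 marks resolved edema.
    """
    meas = []
    for day, ld, edema in scans:
        cr = ld == "CR"
        meas.append(LesionMeasurement(
            patient_id=patient, lesion_id=lesion, days_from_srt=day,
            ld_mm=None if cr else ld,
            perp_mm=None,
            edema_cm3=edema,
            core_present=not cr,
            edema_resolved=edema == 0.0))
    return LesionSeries(patient_id=patient, lesion_id=lesion,
                        measurements=meas, baseline_ld_mm=baseline_ld,
                        baseline_edema_cm3=baseline_edema, **series_kw)


def random_blob_mask(rng, max_slices=3, max_side=18, p=0.35):
    """Small random binary mask, guaranteed nonempty."""
    shape = (int(rng.integers(1, max_slices + 1)),
             int(rng.integers(2, max_side)),
             int(rng.integers(2, max_side)))
    vox = (rng.random(shape) < p).astype(np.uint8)
    if not vox.any():
        vox[tuple(d // 2 for d in shape)] = 1
    return vox


def bruteforce_ld(voxels, spacing):
    """Independent all-pairs longest in-plane diameter oracle (mm)."""
    _, sr, sc = spacing
    best = 0.0
    for s in range(voxels.shape[0]):
        pts = np.argwhere(voxels[s]).astype(float)
        if len(pts) == 0:
            continue
        pts = pts * np.array([sr, sc])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                dx = pts[i][0] - pts[j][0]
                dy = pts[i][1] - pts[j][1]
                d = np.sqrt(dx * dx + dy * dy)
                if d > best:
                    best = float(d)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20230930)
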