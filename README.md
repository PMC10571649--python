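# ranovol

Response assessment for irradiated brain metastases, combining the
standard diameter-based RANO-BM criteria with peritumoral edema
volumetrics.

After stereotactic radiotherapy (SRT), brain metastases are followed
with serial MRI. The reference standard, RANO-BM, tracks the longest
axial diameter (LD) of the contrast-enhancing tumor core: a lesion is
*measurable* if LD ≥ 10 mm with a perpendicular diameter ≥ 5 mm, a
*partial response* (PR) is a decrease ≥ 30 % in LD from baseline,
*progressive disease* (PD) an increase ≥ 20 % from the nadir,
*complete response* (CR) disappearance of the core, and up to five
target-lesion LDs are summed per patient. The FLAIR-hyperintense
peritumoral edema, which often drives neurological symptoms, is ignored
by these criteria. `ranovol` measures both quantities from binary
segmentation masks, grades edema volume change on a ±25 % stability
band (stable / decreased / increased / resolved), labels whether the
core and edema response curves move *congruently* at each follow-up
window — (0,90], (90,180], (180,270], (270,365], (365,∞) days
post-SRT — and classifies whole edema trajectories (continuous
decrease, waxing-and-waning, paradoxical early increase, continuous
increase, complete remission). A calibrated simulator generates whole
cohorts with hidden ground truth so every stage is testable without
patient data.

Intended users: neuro-imaging researchers evaluating volumetric
response criteria, and methodologists who need a transparent, tested
reference implementation of per-lesion RANO-BM-style classification.

## Worked example

Simulate a 20-patient cohort and run the full analysis:

```sh
ranovol simulate -n 20 --seed 7 -o demo
ranovol analyze demo/cohort.csv -o demo_out
```

`simulate` prints the calibration report (realised vs target medians):

```
           variable   n    median        q1        q3  target_median  target_q1  target_q3
lesions_per_patient  20  5.000000  3.000000  8.000000            4.0        3.0       10.0
     baseline_ld_mm 130 12.900606 10.763096 15.757987           14.0       11.0       17.0
 baseline_edema_cm3 130  3.289065  0.613303 30.335685            8.1        0.8       50.0
```

(the generator draws baseline LD from a log-normal with median 14 mm and
IQR 11–17 mm, baseline edema with median 8.1 cm³ and the very wide IQR
0.8–50 cm³, and a log-normal number of lesions per patient; at n = 20
patients the realised medians wobble, at n ≥ 200 they sit within 15 % of
target). `analyze` applies the eligibility rules (baseline LD ≥ 10 mm,
slice thickness < 3 mm, FLAIR available, NSCLC histology; confluent
edema is kept for LD analyses but dropped from edema analyses), then
prints the congruence ratio per follow-up window:

```
window  n  n_congruent  n_incongruent  pct_incongruent
    W1 84           52             32        38.095238
    W2 71           55             16        22.535211
    W3 52           42             10        19.230769
    W4 52           40             12        23.076923
    W5 41           31             10        24.390244
```

so at the first follow-up 32/84 lesions (38 %) changed incongruently —
core shrinking while edema grew, or vice versa. `demo_out/report.json`
also carries the edema trajectory pattern counts and the pooled Spearman
correlation between LD and edema volume over all lesion-timepoints
(here ρ = 0.52, p < 1e-27, n = 384 pairs). Flat tables
(`lesion_window_labels.csv`, `response_curves.csv`,
`window_summaries.csv`, `tests.csv`, `steroid_summaries.csv`,
`exclusions.csv`) hold the per-lesion labels, the relative-size response
curves, median/IQR summaries per window, signed-rank comparisons of
baseline vs each window, and the steroid-stratified summaries.

Masks are measured directly with `ranovol measure core.nii.gz
--edema-mask edema.nii.gz --patient P1 --lesion L1 --day 0 -o rows.csv`,
which appends LD / perpendicular / edema volume rows to a cohort CSV.

The same operations are available as a library:

```python
from ranovol import simulate_cohort, analyze_cohort

cohort = simulate_cohort(20, seed=7)
result = analyze_cohort(cohort.table)
print(result.congruence_by_window)
```

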