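# Methods

## Geometry from binary masks

A lesion mask is a binary grid with axis order (slice, row, column) and
per-axis voxel spacing in mm; the first axis must stack axial slices
(the NIfTI reader transposes the usual x,y,z layout accordingly). The
longest axial diameter (LD) is the maximum voxel-centre-to-voxel-centre
Euclidean distance within any single slice, using the in-plane spacing
per axis; the perpendicular diameter is the width of that slice's
voxel centres projected on the unit normal of the LD segment. Volume is
the voxel count times the voxel volume.

Centre-to-centre distances underestimate an edge-to-edge caliper by at
most one in-plane pixel; we accept that bias for reproducibility. For
slices with more than 50 foreground voxels the all-pairs search is
restricted to convex-hull vertices, which is exact: diameter endpoints
of a planar set are hull vertices, and because squared distance is
strictly convex along a hull edge, a tie at the maximum can never
involve a non-vertex point. Ties across slices are broken toward the
lowest slice index, then the lexicographically smallest endpoint pair.
Degenerate masks (single voxel, or a single in-slice line) return 0 mm
diameters with a "sub-voxel lesion" warning rather than an error: such
lesions are simply non-measurable. An entirely empty mask raises for
diameters and measures 0 cm³ for volume. Disconnected components are
treated as one lesion — lesions are assumed pre-identified by a reader,
and no connectivity analysis is done. Percent-change threshold
comparisons carry a 1e-9 tolerance so that a measurement lying exactly
on an inclusive boundary (9.8 mm from a 14 mm baseline is exactly
−30 %) classifies on the inclusive side despite binary floating point.
The projection width is clamped to the diameter, which bounds it
mathematically, to absorb rounding when the two coincide (a square's
diagonals).

## Cohort model

One table row is a lesion at a timepoint; days count from the SRT
treatment day. The core baseline is the day-0 scan; the edema baseline
is the latest scan within 30 days before treatment (FLAIR is not
acquired intraprocedurally), choosing the scan closest to day 0 when
several qualify because it best reflects the pre-treatment state.
Follow-up windows are right-closed: (0,90], (90,180], (180,270],
(270,365], (365,∞) days; when several scans fall in one window the
earliest is analysed (a declared convention — with 6–12-week scan
intervals this is usually moot). Lesions first seen after day 0 are new
lesions: their first appearance becomes their baseline for later
relative metrics, and the appearance timepoint itself contributes no
relative value.

Eligibility rules are applied in a fixed order with first-match
logging: (3) slice thickness ≥ 3 mm or missing FLAIR, (4) non-NSCLC
histology, (5) baseline LD < 10 mm (new lesions are exempt from rule 5,
having no treatment-day scan to judge). Lesions with confluent
peritumoral edema stay in the diameter analyses but leave the
edema-volume analyses, since their edema cannot be attributed to one
core. The filter is idempotent and each removed lesion appears exactly
once in the log.

## Classification

RANO-BM-style categories are evaluated in precedence order NEW → CR →
PD → PR → SD. PD is checked before PR (progression trumps response, the
usual convention), so a lesion regrowing ≥ 20 % from a deep nadir is
progressive even while still ≥ 30 % below baseline. The nadir at a
timepoint is the minimum of the baseline LD and all strictly earlier
follow-up LDs; after a CR the nadir is treated as 0, so any
reappearance is progression (logged as PD like any other). CR requires
an explicit core-absent flag from the reader or mask, not an
LD-below-resolution heuristic. All thresholds (30 / 20 / 25 / 10 / 5)
are configuration values with these defaults; boundary inclusivity
follows their usual statement (≥ for PR/PD/measurability, strict
"less than 25 %" for the stable edema band, so ±25 % exactly is the
directional grade).

Direction labels (increasing / decreasing / remitted / unchanged)
compare each selected window measurement with the previous available
one (baseline for the first), reproducing the slope of a drawn response
curve rather than a comparison to baseline. An optional epsilon band
(default 0) can absorb small relative changes into "unchanged". A
window is congruent iff both directions are equal and in {increasing,
decreasing, remitted}; under the strict reading a pair of "unchanged"
directions is incongruent, but this is configurable
(`unchanged_pairs_congruent`) because qualitative curve reading may
plausibly treat near-flat pairs as congruent.

Trajectory patterns are labelled on the full scan-level series of
relative sizes (baseline = 100 %), with a declared precedence (first
match wins): complete remission (final value 0), continuous decrease
(all changes ≤ 0), continuous increase (all changes ≥ 0 and final above
baseline), paradoxical-then-decrease (first change up, second down, all
later ≤ 0), waxing-and-waning (a decrease, then at least one regrowth
and a later decrease, never exceeding the pretreatment value), else
other. Fewer than two follow-ups yields "other" with an
insufficient-timepoints note.

The patient-level sum of LD fixes up to five target lesions at
baseline — the largest measurable ones, where a recorded perpendicular
below 5 mm disqualifies but a missing perpendicular does not (LD
tracking does not require it, and follow-up perpendiculars are often
unrecorded) — and is undefined for a window in which any target lesion
lacks a scan; CR targets contribute 0.

## Statistics

All tests are two-sided at α = 0.05, with no multiple-testing
correction (matching the descriptive analysis the package reproduces).
Medians and IQRs interpolate linearly between order statistics (the
common default; printed IQRs cannot adjudicate a convention). The
Wilcoxon signed-rank test drops zero differences (reported n is after
dropping) and uses the exact null for n ≤ 25 without tied absolute
differences, otherwise the tie-corrected normal approximation; the
Mann-Whitney U test is exact for min(n) ≤ 8 without ties. Spearman
correlation uses average ranks, with an exact permutation p-value for
n ≤ 10 (full enumeration, vectorised in chunks) and the t-approximation
above. The pooled LD-vs-edema correlation deliberately pools all
lesion-timepoints across patients, ignoring within-lesion dependence —
it is flagged as such and should be read descriptively. Cross-window
paired comparisons use the intersection of lesions present in both
windows. scipy.stats provides the test engines; the exact small-sample
p-values are verified in the test suite against independent brute-force
enumeration of sign assignments, label assignments and rank
permutations.

## Synthetic data

Phantoms digitise spheres/ellipsoids by voxel-centre inclusion; the
edema mask is the union of the edema ellipsoid with the core. A phantom
whose surface extends beyond the range of voxel centres is rejected
rather than silently clipped. Voxelised volumes converge to the
analytic 4/3·π·abc as spacing shrinks (checked at 2, 1, 0.5 mm).

The cohort simulator emulates: log-normal lesions per patient (median
4, IQR 3–10), log-normal baseline LD (median 14 mm, IQR 11–17) and
baseline edema volume (median 8.1 cm³, IQR 0.8–50), each parameterised
by matching median and IQR on the log scale; a Gaussian copula couples
the two baselines (default correlation 0.75) so bigger cores carry more
edema while both marginals are preserved. Each lesion draws an edema
trajectory pattern from a mixture calibrated to observed proportions
(of 31 followed lesions: 11 continuous decrease, 6 waxing-waning, 4
paradoxical, 3 complete remission, 7 continuous increase) and realises
it with per-scan multiplicative steps chosen to satisfy the pattern
definition exactly in the noiseless limit (waxing regrowth is capped at
85 % of baseline so the never-exceeds-baseline clause holds with
measurement noise). Scans occur at 6–12-week intervals for up to seven
follow-ups, with a per-interval dropout hazard of 0.109 so about half
of the patients end before the seventh follow-up. Core-LD trajectories
follow the edema direction with log-magnitude elasticity 0.5, flipped
to the opposite direction at the first follow-up with probability 0.32
and with probability 0.2 later; a fraction of remission-pattern lesions
also lose their enhancing core (CR). About 18 % of lesions carry
confluent edema, and occasional new lesions appear at the second
follow-up. Steroid exposure is a per-patient, per-window Bernoulli flag
with window probabilities (0.50, 0.41, 0.18, 0.30, 0) and 0.65
peri-SRT. Measurement noise is multiplicative log-normal with
coefficient of variation `noise_cv` (default 0.05, a declared
assumption — no within-lesion repeat-measurement noise level is
available to calibrate against).

Ground truth: the generating edema pattern per lesion, and per-window
congruence labels computed from the noiseless values by plain sign
logic that is written independently of the classification module. With
`noise_cv=0` and no dropout the pipeline recovers both truths for 100 %
of analysed lesions; with `noise_cv=0.05` pattern recovery stays ≥ 90 %
(regression-tested at fixed seeds). Under dropout a truncated series
may no longer exhibit its generating pattern (e.g. a waxing lesion cut
after one follow-up) — the truth table keeps the generating label, and
recovery guarantees apply only without dropout. What passing these
tests shows is that the measurement plumbing, baseline rules, window
selection and classifiers are mutually consistent and correctly
implemented; it does not show that real reader-placed calipers or
manual segmentations would behave this way (automated mask calipers are
a stand-in for manual placement), nor that the trajectory taxonomy is
clinically exhaustive.

## Problem sizes and determinism

The test suite simulates cohorts of up to 500 patients (≈ 3 000 lesions,
≈ 29 000 table rows), which analyses in a few seconds; brute-force
statistical oracles enumerate up to 2⁸ sign assignments, C(16,8) label
assignments and 8! rank permutations. All randomness flows from
explicit integer seeds; simulate → analyze is byte-identical across
runs with the same seed and configuration.

## Known limitations

- No intensity-based segmentation, registration, or DICOM handling:
  inputs are binary masks or pre-measured tables.
- Patient-level overall RANO-BM response (which integrates clinical
  status and steroid dosing) is out of scope; steroid exposure is a
  descriptive grouping flag only.
- The congruence definition leaves the both-unchanged case ambiguous;
  the strict reading is the default, see above.
- Whole-series pattern labels assume the observed scans cover the
  pattern; heavily truncated series fall into "other".
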