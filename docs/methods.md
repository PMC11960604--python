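# Methods

`synpet` implements noninvasive (reference-tissue) quantification for
dynamic SV2A PET and the downstream cohort statistics, together with a
fully seeded synthetic-data generator so the whole pipeline is testable
without acquired scans. This note records the models, the default
parameters and why they were chosen, and what the synthetic data do and
do not establish.

## Timing and containers

All internal times are minutes post-injection; sidecar files carry
seconds and are converted at the boundary (kinetic rate constants are
conventionally quoted per minute). A frame belongs to an averaging
window when its *midpoint* lies inside it; on the standard 35-frame,
90-minute schedule (`4x15,8x30,9x60,2x180,10x300,2x600` seconds) this
puts exactly the two 600-s frames (mid-times 75 and 85 min) in the
70–90-min window. Truncated acquisitions (33–34 frames) are accepted;
operations needing later frames raise rather than extrapolate. Running
integrals anchor at (0, 0): tracer is absent before injection. Default
least-squares frame weights are proportional to frame duration (longer
frames average more counts); uniform weights are available.

## SRTM / SRTM2

The simplified reference tissue model writes a target curve as
`CT = R1*CR + phi*[CR ⊗ exp(-k2a t)]`, with derived quantities
`k2 = phi + R1*k2a`, `BPnd = k2/k2a - 1`, `k2' = k2/R1`, and
`DVR = BPnd + 1`. SRTM2 fixes k2' to a supplied (population) value,
constraining `k2 = R1*k2'` and leaving one linear amplitude per
candidate k2a.

Fitting is by basis functions: the convolution is evaluated on a
0.05-min uniform grid (reference curve linearly interpolated, anchored
at zero activity at injection) with the exponential kernel applied as a
linear recurrence, then sampled at frame mid-times. The k2a search uses
60 log-spaced points on [0.006, 0.6] /min — spanning plausible tracer
kinetics — followed by bounded scalar refinement in log space
(tolerance ~0.2% in k2a). A minimum on the grid edge is flagged
`at_boundary` and excluded from k2' pooling. Bases are memoized per
reference region, since every cortical ROI of a subject shares them.

### Subject k2' pooling

The per-subject reference clearance is the unweighted mean of regional
`k2/R1` over fits surviving plausibility filters: not at the grid
boundary, `BPnd > -0.5`, finite and positive, and within 5 median
absolute deviations of the regional median. The MAD screen exists
because `k2/R1` is a ratio of noisy estimates and is heavy-tailed: a
couple of wild regional values (an order of magnitude off) otherwise
dominate the mean, while the bulk of the distribution sits tightly
around the truth. Noiseless behavior is unchanged by the screen.

## Reference Logan DVR

The reference Logan transform plots `Y(T) = ∫0^T CT / CT(T)` against
`X(T) = (∫0^T CR + CR(T)/k2') / CT(T)`; after transient equilibrium the
slope is DVR. Frames are included when their mid-time is at or beyond
t* (default 35 min); the integrals always run from injection. The
regression is ordinary least squares without error-in-variables
correction, matching common practice; the resulting noise-induced
negative bias at high noise is documented, not corrected. The
steady-state check compares slopes over 35–90 and 70–90 min on the same
points; the late window holds exactly two points on the standard
schedule, so its slope is a two-point secant.

## Reference-region sensitivity analysis

For each candidate region the cohort metrics are: late-window (70–90
min) SUV per subject; per-subject k2' (SRTM pooling above); and the
mean SRTM2 SSE over cortical ROIs at that subject's k2'. Candidates are
ranked on four lower-is-better criteria — mean SSE, and the population
coefficients of variation of SSE, k2' and SUV — with ties sharing mean
ranks, an unweighted mean of the four ranks as the aggregate (no
combination rule is standard, so the simplest symmetric one is used),
and exact aggregate ties broken by mean SSE so the winner is
deterministic and order-invariant. Outlier exclusion for the SUV-age
correlation is an explicit, logged, user-supplied list — never
automatic.

## SUVR windows

SUVR is the ratio of window-averaged target to reference activity.
Candidate windows (50–70, 60–80, 70–90 min) are compared against Logan
DVR two ways: pooled OLS of SUVR on DVR over all subject-by-ROI pairs
(regression direction is a documented convention; R² itself is
symmetric), and per-subject R² across that subject's ROIs. The selected
window maximizes mean within-subject R², tested by a repeated-measures
ANOVA over the aligned per-subject vectors with Tukey-corrected
pairwise contrasts; pooled R² and |slope − 1| are reported as secondary
descriptors. Whether |pooled slope − 1| decreases monotonically with
window midpoint depends on the washout kinetics, so it is reported, not
asserted.

## Partial-volume correction

The two-compartment (tissue vs CSF) correction divides a static image
by the point-spread-blurred binary tissue fraction, suppressing (NaN)
voxels whose fraction falls below a floor. Defaults: isotropic Gaussian
PSF of 6 mm FWHM and floor 0.2, both configurable. Convolution uses
zero padding renormalized by the blurred all-ones mask, so a full mask
maps to unity everywhere. The correction is exact on a phantom blurred
with the same PSF; on real data accuracy is limited by PSF mismatch and
segmentation error. The same dilution formula is exposed at ROI
granularity (`value / regional tissue fraction`) for table-level
workflows; the three-compartment (gray/white) and geometric-transfer-
matrix variants are out of scope.

## Statistics

One-way ANOVA and the repeated-measures (subject-blocked, one
within-factor) ANOVA are computed from their sum-of-squares
decompositions, with the condition effect tested against MS_residual at
(k−1, (k−1)(n−1)) df; Tukey-corrected pairwise p-values use the
studentized range with the relevant error term (Tukey–Kramer for
unequal group sizes). Degenerate inputs (all values equal) report F = 0
and p = 1. Group inference on per-subject spatial correlations runs on
raw r by default, with Fisher-z as an option. Regressions (amyloid
association with a diagnosis interaction; MMSE on volume, uptake, their
product, and age) are OLS with two-sided coefficient t-tests and
adjusted R². All alphas default to 0.05; no correction beyond Tukey
where stated. Exclusions (e.g. a low-MMSE participant) are explicit
lists recorded in the output.

## Synthetic cohort

The generator emulates a three-group study — 7 young (Y), 14 older (O),
7 patients — on the 35-frame schedule. Tissue curves are one-tissue-
compartment responses to a Feng-style plasma input (delay 0.7 min; ramp
amplitude 851.1, washout amplitudes 21.9 and 20.8; rates 4.134, 0.119,
0.0104 /min; global scale 0.072 chosen so the reference late-window
uptake lands near typical SUV magnitude, ~4.4). Frame values are
interval averages, as scanners report them; midpoint sampling is an
option. Radioactive decay is not modeled (frames are assumed
decay-corrected).

The generating reference region (`cereb_gm`) is a pure 1TC tissue
(K1' = 0.3, k2' = 0.055 /min, with modest between-subject lognormal
jitter), so SRTM holds exactly for it and the ground-truth DVR of a
target is `(K1/k2)/(K1'/k2')`. The alternate candidates
(`cereb_whole`, `wm_eroded`) are two-component tissue mixtures whose
mixing fractions and component kinetics vary more between subjects, as
heterogeneous mixed-tissue regions do anatomically — they therefore fit
the single-compartment model worse *and* are less stable across the
cohort, which is the contrast the ranking is designed to detect.

Cortical targets cover the 34 bilateral cortical parcels plus the
bilateral amygdala (for the 6-region temporal meta-ROI), with per-ROI
baseline DVR in [1.5, 2.3], apparent efflux in [0.02, 0.08] /min, and
group DVR multipliers Y 1.0 / O 0.9 / patient 0.75 — chosen to mirror
the qualitative ordering (highest binding in the young, lowest in
patients), not any particular printed value. Frame noise is Gaussian
with SD `sigma0 * sqrt(max(value, eps)/duration_min)`, sigma0 = 0.15 by
default (~2% on late 10-min frames, ~13% on the earliest 15-s frames —
plausible for regional curves). Demographics follow the three-group
design (ages ~26/80/66 y); MMSE comes from a linear model with a
negative volume-by-uptake interaction (binding buffers atrophy);
centiloid, in the amyloid-positive subset, is a negative linear
function of global binding; tau tables are anticorrelated with regional
binding in patients (rho = −0.5) and independent in controls. All
randomness derives deterministically from the master seed.

Partial-volume effects enter at the table level: each subject x region
carries a gray-matter fraction (group means 0.95/0.88/0.80), the
pipeline's "observed" ratio tables are diluted by it, and the PVC stage
corrects with the same two-compartment formula. Simulated TACs are kept
kinetically clean so noiseless estimators recover the generative
ground truth exactly; image-space PVC is validated separately on
blurred phantoms. Consequences: passing tests demonstrate estimator
correctness and internal consistency of the workflow, not robustness to
real-scanner effects (scatter, motion, PSF mismatch, 2TC target
kinetics, perfusion differences across windows), which the generator
deliberately omits.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run cohorts of 10–28
subjects, a 20-seed panel for reference-region ranking, 200-replicate
noise studies for estimator bias, 1000-replicate null simulations for
the type-I calibration of the repeated-measures ANOVA and the
age-correlation test, and 40-voxel-cube phantoms for PVC. These sizes
were picked so every check runs comfortably on a single CPU while
keeping Monte-Carlo error well below the asserted tolerances.

## Known limitations

* SRTM/SRTM2 assume both tissues are well described by single
  compartments and a shared input; when the reference region carries
  displaceable binding, DVR no longer equals BPnd + 1 and all derived
  quantities are interpretable only comparatively.
* Logan OLS has a known negative bias at high noise; no
  error-in-variables correction is applied.
* The PVC is the CSF-dilution (two-compartment) variant only.
* The synthetic MMSE/centiloid/tau models are linear with Gaussian
  noise; they exercise the statistics, not clinical realism.
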