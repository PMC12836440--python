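# Methods

## The measurement pipeline

A condylar ROI (default 100 × 100 px, anchored by an operator-supplied
top-left `(x, y)` in 0-based row/column coordinates with half-open
windows) passes through ten steps:

1. ROI extraction; 2. duplication; 3. Gaussian blur of the duplicate;
4. subtraction of the blurred image from the duplicate; 5. addition of
128 gray levels; 6. fixed-threshold binarization; 7. erosion;
8. dilation; 9. inversion; 10. skeletonization.

Steps 3–5 are a background correction: the blur estimates the
large-scale density trend of the radiograph, the subtraction leaves the
fine trabecular texture, and the +128 offset recenters it on mid-gray.
Steps 7–8 are a morphological opening that removes binarization
speckle; inversion makes the intertrabecular network the foreground,
and thinning reduces it to 1-pixel-wide curves whose box-counting
dimension is the FD.

The skeleton is covered with grids of edge ε anchored at the top-left
corner (partial edge cells count; a single fixed grid, no offset
averaging), and FD = −slope of the unweighted OLS fit of log N(ε) on
log ε (natural log; the base cancels in the slope). The default ε
schedule is {2, 3, 4, 6, 8, 12, 16, 32, 64}, capped at the shorter
image side; because FD values are only comparable under one schedule,
every output record echoes the schedule and the preprocessing
configuration used. A post-fit assertion enforces FD ∈ (0, 2]; a fit
outside that range raises a diagnostic rather than returning silently.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `gaussian_sigma` | px | 35 | the established background scale for 100 px dental-radiograph ROIs; large enough that the blur is a density trend, not texture |
| `offset` | gray levels | 128 (fixed) | recenters the zero-clamped difference image on mid-gray |
| `binarize_threshold` | gray level | 128, strict `>` | after the +128 recentering, "brighter than background" is exactly `> 128` |
| `morphology_radius` / `iterations` | px / count | 1 / 1 (3 × 3 square) | the common macro default; one opening pass removes speckle without erasing trabeculae |
| box sizes | px | {2,…,64} | geometric-ish ladder spanning ~1.5 decades on a 100 px ROI |
| `rho` (cohort simulator) | – | 0.5 | within-subject left/right FD correlation; unreported in the source tables, so it is exposed and documented rather than hidden |

Numerical conventions: 8-bit saturating arithmetic for subtract/add;
edge replication for the blur; out-of-image neighbours are background
for both erosion and dilation (the exact erosion/dilation duality holds
under the mirrored, foreground-padded erosion, available via
`erode(..., border="foreground")`); skeletonization is Zhang–Suen-type
thinning preserving 8-connected component count. Every trace is a pure
function of (pixels, config).

Degenerate inputs: if nothing survives the opening (e.g. a flat ROI),
the trace is flagged degenerate and the inversion/skeleton steps are
left empty — inverting an empty mask would otherwise manufacture a
spurious border skeleton — and the end-to-end measurement raises a
"degenerate ROI" error instead of emitting a number. An all-foreground
post-opening mask needs no special case (its inversion is empty).

## Synthetic data

`make_sierpinski_carpet`, `make_line`, and `make_filled_rect` are
closed-form fixtures with known dimensions (log 8/log 3, 1, 2) used to
validate the estimator. `make_trabecular_texture` is band-pass-filtered
Gaussian noise rescaled to 8 bits; its `complexity` parameter shrinks
the dominant feature scale from ~8 px to ~1 px, which raises the
end-to-end FD monotonically (medians 1.06 → 1.19 → 1.61 at complexity
0 / 0.5 / 1 over 20 seeds). It emulates the spatial-frequency content
of trabecular texture, not its anatomy: no cortical margins, no
superimposed airway or anatomical shadows, no osteophytes or cysts, no
machine-specific noise. Passing tests therefore establish estimator
correctness and pipeline behaviour on texture-like inputs, not clinical
performance on radiographs.

`simulate_cohort` draws one row per subject from the published per-cell
design: 110 TMD patients and 110 controls across four age bands
(18–29, 30–39, 40–49, ≥50, ages uniform within band, capped at 75) and
two genders, with per-cell (LC_FD, RC_FD) means and SDs taken from the
published descriptive tables. Pairs are jointly normal with correlation
`rho`, truncated to (0, 2] by rejection — a model consistent with the
published normality results (one non-normal cell out of sixteen).
The control tables print conflicting gender counts between their left-
and right-condyle rows; the simulator uses the left-condyle counts,
since one row per subject admits only one design. Simulated cohorts
reproduce the configured moments (law-of-large-numbers tests) but are
not the study's subjects: cohort-level results on real radiographs
(e.g. a specific AUC) are not reproducible from them, and the test
suite asserts signal-detection and calibration properties instead.

## Statistics

Per-cell descriptives use sample SD (n−1); empty strata are reported
with n = 0 and single-subject strata flag the SD undefined rather than
dropping rows. Group comparisons are gated: Shapiro–Wilk on each arm at
α = 0.05; both normal → equal-variance independent t-test (consistent
with the pooled-SD Cohen's d reported alongside; Welch is available by
flag), otherwise two-sided Mann–Whitney U. Bonferroni correction is
min(1, m·p) with m = 8 for the combined-condyle table, whose tiers are
a presentation rule only: corrected p < 0.05 "Significant (**)",
< 0.005 "Highly Significant (***)". ICC(2,1) is the two-way random,
absolute-agreement, single-measure coefficient with its F-based 95% CI
(computed via pingouin); under perfect agreement the F interval
degenerates and the CI collapses to the point estimate.

The gated comparison is calibrated: under a normal null at n = 26 per
arm its type-I error is 5% (±1.5% band over 2000 simulations in the
acceptance check).

## Classification

One row per subject, features {age, gender (male = 0, female = 1),
lc_fd, rc_fd}, label patient = 1 (the control-positive view of every
confusion matrix is also emitted, since published precision/recall
figures can follow either convention). The 70/15/15
train/validation/test split is stratified by label with
largest-remainder rounding (220 rows → 154/33/33) at seed 42;
z-scoring (population SD) is fit on the training partition only.
Six families run at their library defaults with the seed applied
wherever the family is stochastic, and the defaults actually used are
serialized into the run manifest. Reported metrics are 5-fold
stratified cross-validation over the full standardized matrix
(folds of 44) as mean ± SD, plus point metrics on the held-out
partitions; models are ranked by CV accuracy, ties broken by AUC.
Two runs at the same seed are byte-identical.

On default-design cohorts the boosted models' CV AUC sits near
0.65–0.70 — a clear signal at the published effect sizes, but smaller
than figures reported on real data, as expected for a 4-feature
simulation; on zero-separation cohorts every family's accuracy is
consistent with chance (slightly below 0.5 on single draws, the usual
finite-sample anticorrelation of balanced cross-validation).

## Problem sizes

Unit and acceptance tests use 24–50 px oracle images, 243 px fixtures,
20-seed texture experiments, 2000-replicate null calibrations, and
220-row cohorts (5 replicates for the null classifier check) — sizes
chosen so the full suite completes in well under a minute per layer
while keeping every Monte Carlo band at least ~3 standard errors wide.

## Known limitations

- Physical pixel spacing is not modeled; FD is computed in pixel units
  and is comparable only across images with the same resolution and ROI
  size.
- The binarization threshold is fixed, not adaptive; heavily over- or
  under-exposed ROIs may binarize poorly (the degenerate-ROI guard
  catches the extreme case only).
- ROI placement is operator input; no condyle localization is provided.
- The FD-vs-complexity monotonicity is established on the synthetic
  texture family, not on radiographs.
- DICOM support requires the optional pydicom dependency and rescales
  by the observed intensity range.
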