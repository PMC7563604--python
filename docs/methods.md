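# Methods

## The filtration-histogram model

The technique treats lesion texture as a two-stage measurement. First, a
band-pass filter isolates image structure of a chosen physical size; second,
first-order histogram statistics summarize the filtered intensities inside
the ROI. Because the filter is linear and zero-sum, the filtered statistics
respond to *variation* at that scale and are invariant to the DC intensity
level — which is what makes them comparable across scanners that use
arbitrary intensity units.

The filter is the negative Laplacian of a Gaussian,
−∇²G_σ(r) = (2σ² − r²)/(2πσ⁶) · exp(−r²/2σ²), sampled on the pixel grid,
truncated at radius ⌈4σ⌉ and mean-subtracted so the entries sum to exactly
zero. Mean subtraction (rather than relying on analytic cancellation)
guarantees exact annihilation of constant images after truncation. The sign
convention makes bright blobs produce positive responses, so "mean of
positive pixels" reads as the mean response over bright features.

**Scale mapping.** The spatial scale factor (SSF) is stated in mm of feature
*radius*. A scale-normalized LoG responds maximally to a disc of radius
√2·σ, so we map σ = SSF/√2 (in mm), converted to pixels by the in-plane
spacing. The constant is exposed (`sigma_per_ssf`) because commercial
filtration-histogram implementations do not publish theirs; results at
SSF > 0 are method-faithful but not bit-compatible with any proprietary
tool. A corollary worth stating: the *unnormalized* kernel's maximum
absolute response to a disc always peaks at fine scales (edge response
dominates); the matched-scale selection property ("a disc of radius r is
best enhanced at SSF = r") holds for the σ²-normalized response, and that is
the form our scale-selection test asserts.

**Boundary handling.** The full image is filtered (mirror padding at image
borders) and statistics are then sampled inside the ROI. Filtering the
masked region instead would make boundary ringing a function of mask shape.
Convolution runs via FFT on the reflect-padded image; it matches direct
spatial convolution to ~1e-12, far inside the 1e-6 contract asserted in the
tests. Scales whose σ falls below 0.5 pixel are rejected (unresolvable on
the grid), as are images smaller than the kernel.

## First-order statistics

Over the ROI values of each derived image: arithmetic mean; sample SD
(n−1 — ROIs are small, hundreds of pixels); mean of strictly positive
values (0 + flag when none); Fisher–Pearson skewness g₁ = m₃/m₂^1.5 and
excess kurtosis g₂ = m₄/m₂² − 3 with n-denominator central moments; Shannon
entropy in bits over 256 equal-width bins spanning the ROI's own [min, max].
Zero-variance ROIs yield skewness = kurtosis = entropy = 0 with explicit
flags rather than NaN. ROIs below 9 pixels are rejected: a 4th-moment
estimate from fewer values is noise, and failing loudly beats returning it.

Conventions that the literature leaves open are parameters, not constants:
the kurtosis convention (`excess` vs `pearson`), the entropy bin count, and
the SSF→σ constant. MPP on an unfiltered magnitude image degenerates to the
mean; it is computed anyway so the 24-column table is complete at every
scale.

## Statistical workflow

* **Mann–Whitney U** (benign vs malignant, per feature): U from midrank
  sums; exact two-sided permutation p by full enumeration when the combined
  n ≤ 20 and there are no ties; otherwise the tie-corrected normal
  approximation with a 0.5 continuity correction. Ties always force the
  approximation (midrank exact distributions are not enumeration-stable).
  The implementation is cross-checked against scipy's in both regimes.
* **Kruskal–Wallis** (across the four histological subtypes): tie-corrected
  H against chi-square with k−1 df (delegated to scipy); the all-identical
  degenerate case returns H = 0, p = 1.
* **ROC**: empirical AUC with midrank ties (identical to U/(n₊·n₋), an
  identity asserted to 1e-12 in the tests), oriented so AUC ≥ 0.5 with the
  direction recorded. Candidate cutoffs are midpoints between adjacent
  sorted unique scores; the Youden-maximal cutoff wins, ties broken by
  higher specificity then lower cutoff (in a diagnosis setting false
  positives trigger surgery, so specificity is the natural tie-break). AUC
  CI and the p-value against 0.5 use the DeLong single-curve variance;
  sensitivity/specificity intervals are exact Clopper–Pearson. The Youden
  index is reported both at full precision and truncated (not rounded) to
  two decimals, as clinical tables commonly print it.
* **DeLong comparison**: the structural-components covariance estimator for
  paired curves; verified to 1e-8 against R's pROC and against a 20,000-rep
  studentized marker-swap permutation reference. Scores are compared as
  given; the workflow orients each marker (sign-flip when its direction is
  "less_equal") before comparing, so differences reflect discriminative
  ability.
* **Prediction model**: an "enter" model — all univariately significant
  features enter an OLS regression of the 0/1 malignant label
  simultaneously, with no selection. The linear-probability choice (rather
  than logistic) reproduces the reporting style of small-cohort clinical
  radiomics: coefficients with t-test p-values, R², adjusted R², multiple
  correlation coefficient, overall F significance, and per-predictor
  VIF_j = 1/(1−R²_j). Its fitted score is ROC-analyzed like any marker, with
  the cutoff reported on the raw score. Fitting and evaluation share the
  same subjects — in-sample, as the emulated study design does — so the
  model's AUC is optimistic; the package reproduces the design rather than
  fixing it, and the README says so. When the screen passes more predictors
  than n − 3 the regression is underdetermined; the report then notes the
  fact and skips the model while still reporting per-feature ROC.
* **Screening**: strictly p < α (a feature at exactly α is excluded), no
  multiple-testing correction by default — matching common practice in
  pilot studies, where the screen is descriptive — with an optional Holm
  flag. Medians and IQRs use linear-interpolation (type-7) quartiles; the
  convention matters at n = 13–15 and is stated for that reason.

## Synthetic phantoms

Each subject is a single 128 × 128 slice at 0.75 mm isotropic spacing (the
240 mm / 320-matrix in-plane geometry of a pelvic T2 protocol, cropped to
the lesion neighborhood): a rotated elliptical fluid ROI (full axes drawn
uniformly from 10–25 mm, resampled until it fits, hard error after 100
attempts) on a darker tissue background.

Fluid intensity is `base + amplitude · GRF + noise`, where GRF is a
unit-variance Gaussian random field with squared-exponential correlation
(white noise smoothed with a Gaussian of σ = ℓ/2 pixels, giving correlation
length ℓ). Benign fluid is bright and homogeneous (high base, low
amplitude, ℓ = 2 mm) with sparse dark debris specks (2% of pixels, depth
~52,000·U(0.5, 1.5)): the rare deep outliers below a tight bulk produce the
left-skewed, high-kurtosis histogram of simple fluid. Malignant fluid is
darker and heterogeneous: stronger field (ℓ = 3 mm), no debris, plus a
smooth two-component mixture (35% of area ~21,000 units darker, patches cut
from a thresholded correlated field), producing the broader, flatter
histogram and the larger mid-scale SD. Noise is Gaussian by default — at
fluid SNRs the Rician correction is negligible and Gaussian keeps the
moment calibration analytic — with a Rician option.

Intensity defaults were calibrated once so that (a) the three group-median
orderings that carry the clinical signal hold robustly at the default
15/13 cohort size — malignant SD higher at the medium scale, benign
skewness more negative and kurtosis higher on raw images — and (b) benign
SD at SSF = 4 lands in the hundreds, the magnitude scale typical of
scanner-unit T2 fluid. Magnitudes are cosmetic (they depend on the
unpublished filter-gain convention of commercial tools); orderings are the
calibration target and the only thing the tests assert about them.

Randomness is split-stream: a master seed spawns one child stream per
(group, subject-index), so enlarging a group never perturbs existing
subjects — asserted in the tests. Subtypes are assigned within groups
(10 functional cysts + 5 serous cystadenomas; 8 clear-cell + 5 serous
carcinomas at default counts, proportional otherwise) and share their
group's intensity model: the generator encodes the benign/malignant
contrast, not subtype-level differences, so subtype tests on synthetic data
exercise plumbing, not biology.

A separate mock referral registry reproduces the cohort-selection funnel:
221 records carrying exactly one exclusion flag each (keyword mismatch 14,
artifacts 8, non-pelvic protocol 20, fluid contamination 13, fluid below
15 mm 41, no follow-up 36, no final diagnosis 61, none 28); applying the
cascade leaves the 28 eligible subjects.

**What passing tests do and do not show.** The phantoms reproduce the
*statistical structure* the method assumes — group-specific histogram
shapes, spatial texture at controlled correlation lengths, a fixed cohort
funnel — but not anatomy: no walls, septations or vegetations (the ROI
excludes solid components by design), no partial-volume effects at the
fluid boundary, no bias fields, and intensity distributions far better
separated than a real cohort's. Green tests therefore validate the
pipeline's correctness and calibration recovery, not clinical performance.

## Verification strategy and problem sizes

Every statistical primitive is checked against an independent route: moments
against a direct two-pass reference (1,000 random ROIs, 1e-10 relative);
AUC against the U-statistic identity (500 datasets, 1e-12); the exact
Mann–Whitney p against brute-force enumeration of all labelings (n ≤ 10);
DeLong against pROC and a permutation reference; OLS against hand-computed
closed forms; the filtration against direct spatial convolution and the
analytic kernel expression. The type-I error of the univariate screen is
simulated under a global null (24 Gaussian features, 15 vs 13 subjects,
5,000 replicates; per-feature rejection within [0.03, 0.07] at α = 0.05).
Parameter recovery runs the full pipeline at 200 subjects per group and
compares the kurtosis AUC against an independent Monte-Carlo oracle that
draws ROI pixel sets from the generator's marginal intensity model (spatial
correlation ignored — immaterial at the configured separation); ordering
stability uses 50 default-size cohorts. These sizes keep the whole suite
around a minute on one CPU while leaving each check's Monte-Carlo error an
order of magnitude below its tolerance.

## Known limitations

* Single-slice 2D analysis only; no volumetric ROIs.
* Not bit-compatible with commercial filtration-histogram software (their
  SSF→σ constant, padding and histogram conventions are unpublished).
* The prediction model is evaluated in-sample by design; no cross-validation.
* Entropy depends on the binning convention; comparisons across tools must
  match `nbins`.
* The generator's effect sizes are calibrated to orderings, not to any real
  cohort's effect sizes, which are unknowable from published summaries.
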