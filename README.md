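# cystexture

Filtration-histogram texture analysis of ovarian-cyst fluid on T2-weighted
MRI slices, with the downstream statistical workflow used to separate benign
from malignant cysts, and a synthetic phantom generator so the whole pipeline
runs end-to-end without any patient data.

## Who this is for

Radiomics researchers studying whether the fluid content of cystic lesions
carries diagnostic signal that conventional reading misses. The package
implements the *filtration-histogram* technique: a band-pass
Laplacian-of-Gaussian (LoG) filter extracts image structure at a chosen
spatial scale, and first-order histogram statistics of the ROI quantify the
texture of each derived image. It also implements the full small-cohort
statistics that typically follow: nonparametric group tests, ROC analysis
with Youden-index cutoffs, DeLong comparison of correlated ROC curves, and a
linear-probability "enter" regression whose fitted score acts as a combined
prediction model.

## The method

For an image *I* with isotropic pixel spacing *Δ* (mm) and a spatial scale
factor SSF (mm of feature radius), the derived image at that scale is

```
I_SSF = (−∇²G_σ) * I,      σ = SSF / (√2 · Δ)  pixels
```

the negative LoG kernel (bright blobs → positive response), truncated at
⌈4σ⌉ pixels and mean-subtracted so constant images map exactly to zero.
SSF = 0 denotes the unfiltered image; the default ladder is SSF ∈ {0, 2, 4,
6} mm (fine / medium / coarse texture). Over the ROI pixels of each derived
image, six statistics are computed — mean, SD (sample, *n*−1), Shannon
entropy (bits, 256 equal-width bins), mean of positive pixels (MPP),
skewness g₁ = m₃/m₂^1.5 and excess kurtosis g₂ = m₄/m₂² − 3 — giving the
6 × 4 = 24-value feature set of one lesion.

The analysis workflow on a cohort feature table is: Kruskal–Wallis across
histological subtypes per feature; Mann–Whitney U benign vs malignant per
feature (exact permutation p when combined *n* ≤ 20 and no ties, else
tie-corrected normal approximation with continuity correction); features
with p < α enter an ordinary-least-squares regression of the 0/1 malignancy
label (with per-predictor t-tests and VIFs); ROC curves with DeLong AUC
variance, Youden-optimal cutoffs and Clopper–Pearson sensitivity/specificity
intervals are reported for every significant feature and for the model
score, with all pairwise DeLong comparisons.

## Worked example

```python
import cystexture as ct

# one synthetic benign phantom: bright elliptical fluid on darker tissue
img, mask, group, subtype = ct.generate_cohort(ct.PhantomParams(seed=42))[0]
fs = ct.extract_feature_set(img, mask)
print(group, subtype, mask.n_pixels)
for stat in ("mean", "sd", "skewness", "kurtosis"):
    print(f"{stat}_ssf0 = {fs[(stat, 0.0)]:.2f}   {stat}_ssf4 = {fs[(stat, 4.0)]:.2f}")
```

prints

```
benign functional_cyst 552
mean_ssf0 = 75752.15   mean_ssf4 = 1027.10
sd_ssf0 = 8269.45   sd_ssf4 = 395.70
skewness_ssf0 = -4.43   skewness_ssf4 = -0.19
kurtosis_ssf0 = 30.11   kurtosis_ssf4 = -1.13
```

The strongly negative skewness and high kurtosis on the unfiltered image
(SSF = 0) are the signature of bright, homogeneous fluid with sparse dark
debris: a tight intensity peak with a long left tail. After medium-scale
filtration (SSF = 4) the DC level is gone (mean near zero relative to the
raw scale) and SD measures mid-scale texture energy.

The full pipeline — simulate a 15 benign / 13 malignant cohort, extract the
24 features, run the statistics — is one command:

```bash
cystexture run --out demo --seed 42
```

which writes `features.csv` and `report.json`. On this seed the univariate
screen retains 20 of 24 features; for example the raw-image kurtosis
discriminates perfectly on the synthetic cohort (AUC 1.00, cutoff ≤ 8.18,
sensitivity 100%, specificity 100%), and the enter-model regression reports
R² = 0.995. Synthetic phantoms are deliberately better separated than real
cohorts; the statistics, not the effect sizes, are the point. Subcommands
`simulate`, `extract` and `analyze` run the stages separately (NIfTI images
and masks, CSV tables, JSON report).

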