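# radbiopsy

**MRI-radiomics "virtual biopsy" for melanoma brain metastases.**

Between 40 % and 60 % of melanomas carry an activating BRAF mutation, and a
brain metastasis does not always share the genotype of its primary tumor.
Knowing a metastasis's BRAF status steers targeted therapy, but today it
requires surgical tissue sampling. `radbiopsy` implements a noninvasive
alternative: it converts a routine contrast-enhanced T1-weighted MRI of the
lesion into 195 quantitative radiomic features and classifies the BRAF
status with a cross-validated support vector machine — plus a seeded
synthetic 3D cohort generator so the entire analysis can be built, tested
and calibrated at desk scale without any clinical data.

It is written for imaging scientists and neuro-oncology researchers who want
a transparent, fully reproducible reference implementation of this class of
radiomics pipeline.

## The model

For each lesion, on the volume normalized so that normal-appearing white
matter has mean intensity 1:

| family | n | content |
|---|---|---|
| clinical | 2 | age, gender |
| location | 16 | % of lesion voxels per atlas region (left/right frontal, parietal, temporal, occipital, limbic, sublobar, cerebellum, brainstem) |
| morphology | 9 | volume, equivalent diameter, extent, 3 principal axis lengths, convex volume, solidity, surface area |
| first-order | 12 | mean, median, SD, variance, min, max, percentiles 5/25/75/95, kurtosis, skewness |
| GLCM | 156 | 12 Haralick measures × 13 offset directions, distance 8 voxels, 32 gray levels |

The gray-level co-occurrence matrix (GLCM) for offset direction **o** and
distance *d* is the symmetric joint distribution
P(i, j) ∝ #{(v, v + d·**o**) : both voxels in the lesion, level(v) = i,
level(v + d·**o**) = j}, from which energy Σp², entropy −Σp log₂ p,
correlation, contrast, variance, sum-mean, inertia, cluster shade/tendency,
homogeneity, max probability and inverse variance are computed per offset.

Features differing between BRAF-positive and BRAF-negative lesions
(KS-gated t-test or Mann-Whitney U, p < 0.05) are standardized,
X_SD = (X − X̄)/σ_X̄, reduced by PCA to the components explaining 95 % of
variance, and classified by SVMs with six kernels (linear, quadratic, cubic,
fine/medium/coarse Gaussian) under patient-grouped stratified 5-fold
cross-validation. Reports give per-class precision/sensitivity/specificity,
accuracy (mean ± SD over folds) and the pooled ROC/AUC. Both the original
whole-cohort preprocessing (`whole_cohort`) and a `leakage_free` mode that
refits all preprocessing inside each training fold are first-class; every
report states its mode. See `docs/methods.md` for all conventions.

## Worked example

```python
from radbiopsy import (SyntheticCohortConfig, generate_cohort,
                       VirtualBiopsyModel)
from radbiopsy.pipeline import extract_cohort_features

cfg = SyntheticCohortConfig(seed=42)          # 25 + 29 lesions, 64^3 grid
cases, manifest = generate_cohort(cfg)
features = extract_cohort_features(cases)     # 54 x 195 table

model = VirtualBiopsyModel(features, manifest.labels, groups=manifest.groups)
results = model.fit(kernel="linear", n_folds=5, seed=42)
print(results.summary())
```

```
Virtual biopsy: BRAF-status SVM cross-validation
============================================================
kernel: linear    folds: 5    mode: whole_cohort    seed: 42
lesions: 54 (25 positive / 29 negative)
features selected: 90/195 at p < 0.05
PCA components: 21 (>= 95% cumulative variance)
------------------------------------------------------------
       precision_pos  sensitivity_pos  specificity_pos  precision_neg  sensitivity_neg  specificity_neg  accuracy
fold1          1.000            0.800            1.000          0.857            1.000            0.800     0.909
fold2          1.000            0.400            1.000          0.667            1.000            0.400     0.727
fold3          1.000            1.000            1.000          1.000            1.000            1.000     1.000
fold4          1.000            1.000            1.000          1.000            1.000            1.000     1.000
fold5          1.000            0.800            1.000          0.833            1.000            0.800     0.900
mean           1.000            0.800            1.000          0.871            1.000            0.800     0.907
sd             0.000            0.219            0.000          0.124            0.000            0.219     0.100
------------------------------------------------------------
pooled ROC AUC (positive BRAF): 0.994
pooled confusion: TP=20 FN=5 FP=0 TN=29
```

The synthetic cohort builds in a genuine class difference — BRAF-negative
surrogate lesions have a shorter texture correlation length, hence more
heterogeneous signal — and the pipeline recovers it almost perfectly
(AUC 0.994 here). 90 of 195 features pass the univariate screen, mostly
co-occurrence features, and 21 principal components cover 95 % of their
variance. On a *null* cohort (identical class parameters) the leakage-free
AUC falls to ≈ 0.5, while the whole-cohort mode stays optimistic — which
is exactly why reports are labeled with their mode.

For file-based workflows there is a small CLI:

```bash
radbiopsy synth --seed 7 --out cohort/          # NIfTI volumes + manifest.csv
radbiopsy extract --manifest cohort/manifest.csv --out features.csv
radbiopsy run --seed 7 --out results/           # full pipeline, all kernels
radbiopsy report --out-dir results/
```

`run` also accepts `--config cfg.yaml`, a flat key:value file
(`seed`, `mode`, `alpha`, `variance_threshold`, `n_folds`, `kernels`,
`glcm_distance`, `glcm_levels`, `manifest`, and `synthetic_*` keys mirroring
the `SyntheticCohortConfig` fields, e.g. `synthetic_n_positive: 25`).

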