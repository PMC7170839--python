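# Methods

`radbiopsy` implements an MRI-radiomics "virtual biopsy": given a
contrast-enhanced T1-weighted brain volume, a lesion segmentation, a
normal-appearing-white-matter (NAWM) reference mask and a 16-region atlas in
subject space, it predicts whether a melanoma brain metastasis carries an
activating BRAF mutation. This note documents the model, its conventions and
tunable parameters, the synthetic cohort the tests run on, and the design
choices made where several readings were defensible.

## Pipeline

1. **Intensity normalization.** Every voxel is divided by the arithmetic
   mean intensity over the NAWM reference mask, so lesion intensities are
   expressed relative to normal white matter (the reference mean becomes 1).
   The mean, rather than the median, is used as the conventional reference
   statistic. No resampling is performed; volume, masks and atlas must share
   the grid exactly (shape and spacing).

2. **Feature extraction** — 195 features per lesion, in five families:

   * *clinical* (2): age in years, gender code.
   * *location* (16): percent of lesion voxels in each of the 16 left/right
     lobar, cerebellar and brainstem atlas regions. Percentages sum to 100
     only when every lesion voxel carries a region code.
   * *morphology* (9): volume (mm³), equivalent spherical diameter
     ((6V/π)^{1/3}), extent (volume / bounding box), three principal axis
     lengths 2√(5λᵢ) from the eigenvalues of the physical voxel-coordinate
     covariance (the uniform-ellipsoid second-moment equivalence, validated
     against digital balls), convex-hull volume, solidity, and the
     triangulated 0.5-isosurface area (mm²). Multi-component masks are
     reduced to the largest 26-connected component with a warning.
   * *first-order* (12): mean, median, SD, variance (both n−1), min, max,
     percentiles 5/25/75/95 (linear interpolation between order statistics),
     kurtosis (biased, non-excess: normal → 3) and skewness (biased). A
     zero-variance lesion yields 0 for both moments with a warning.
   * *GLCM* (156): 12 Haralick-style measures × 13 offsets. In-lesion
     intensities are quantized into 32 equal-width bins between the
     in-lesion min and max (range-relative, hence invariant to positive
     intensity scaling); levels are 1..32, with 0 as the out-of-lesion
     sentinel. For each of the 13 canonical half-neighborhood directions,
     pairs (v, v + d·offset) with both voxels in the lesion are accumulated
     symmetrically and normalized. The displacement multiplier d is 8 grid
     steps and applies per component, so diagonal offsets are longer in
     Euclidean terms; this multiplier reading of "distance" is a declared
     convention. Entropy uses log base 2 with 0·log 0 ≡ 0; "contrast" and
     "inertia" share one formula (both names are kept, preserving the
     12 × 13 = 156 inventory); a GLCM with zero valid pairs propagates NaN,
     and such features are skipped by the univariate screen. Correlation of
     a single-level GLCM is defined as 0.

3. **Univariate screening.** Per feature, a one-sample Kolmogorov–Smirnov
   test of the z-scored values against the standard normal is run in each
   class; if both classes look normal (p ≥ 0.05) a pooled-variance t-test is
   used, otherwise the Mann-Whitney U test with the tie-corrected normal
   approximation and *no* continuity correction (so identical samples give
   p = 1 exactly). Features with p < α = 0.05 are retained, uncorrected for
   multiplicity; a Benjamini–Hochberg option exists but is off by default to
   match the original uncorrected screen.

4. **Standardization and PCA.** Selected features are centered on the cohort
   mean and scaled by the cohort sample SD (divisor n−1). PCA is an
   eigendecomposition of the resulting covariance; eigenvalues below 1e−12
   of the total are discarded as rank deficiency, component signs are fixed
   by making each component's largest-magnitude loading positive, and the
   smallest k with cumulative explained variance ≥ 95 % is retained.

5. **Classification.** A soft-margin SVM (box constraint 1, threshold at the
   natural 0) on the k component scores, in six kernel variants: linear,
   polynomial of degree 2 and 3 (inhomogeneous, (x·y + 1)^d), and Gaussian
   with kernel scale √P/4, √P, 4√P for P input dimensions (the
   fine/medium/coarse convention). Evaluation is 5-fold cross-validation
   with folds built at the *patient* level, stratified by class: patients
   are shuffled with the seed and dealt class-by-class to the fold holding
   the fewest patients of that class, so fold sizes differ by at most one
   patient and both genotypes appear in every fold when feasible.

6. **Metrics.** Per fold: per-class precision, sensitivity and specificity
   (the classes swap roles for the negative block, so negative-class
   sensitivity equals positive-class specificity identically) and accuracy.
   Summaries are mean ± *population* SD (divisor n_folds); this convention
   reproduces the published fold-summary arithmetic, where the sample-SD
   convention does not. The ROC is built from decision values pooled across
   validation folds (per-fold AUCs are also reported) and the AUC by
   trapezoidal integration, which equals the tie-corrected pairwise ranking
   statistic. Undefined precision (a class never predicted) is reported as 0
   with a warning flag.

## Evaluation modes and leakage

The original analysis fits screening, standardization and PCA on the whole
cohort *before* cross-validation. That design is reproduced faithfully as the
`whole_cohort` mode, and every report is labeled with its mode, because the
shared preprocessing has seen the validation labels and inflates fold
metrics: on pure-noise cohorts the whole-cohort linear-SVM AUC typically
lands between 0.65 and 0.85 instead of 0.5. The `leakage_free` mode refits
all three stages inside each training fold and is the unbiased estimate of
generalization; it is the mode used for the null-calibration checks, since
calibration is a property of the unbiased estimator, not of the leakage.
Folds that select no significant feature fall back to the single smallest-p
feature so the classifier always has an input.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, at
desk scale, with every draw derived from one master seed via counter-based
`SeedSequence` spawns (bit-reproducible across platforms):

* 25 BRAF-positive and 29 BRAF-negative lesions by default, one lesion per
  patient (an optional flag attaches a second lesion to one negative patient
  to exercise group-aware folding); ages 55 ± 14 vs 64.4 ± 12.3 years.
* a 64³ grid at 1 mm isotropic spacing; a 2×2×4 rectangular-block atlas over
  the grid interior stands in for the stereotactic parcellation;
* an axis-aligned ellipsoidal lesion (radii uniform in 8–12 voxels) centered
  in an atlas region drawn from a class-specific categorical prior — the
  positive class favours two regions, the negative class a third, echoing
  the reported location differences in direction only;
* lesion texture: white noise smoothed at a class-specific correlation
  length, standardized, mapped through the normal CDF and rescaled — a
  Gaussian-copula random field with a bounded uniform marginal. The marginal
  transform matters: with raw Gaussian marginals, the sample extremes of
  rough fields stretch the range-relative quantization grid and GLCM entropy
  becomes non-monotonic in the correlation length; with the uniformized
  marginal, both classes share one first-order distribution and entropy is
  strictly monotone, so the co-occurrence features carry exactly the
  intended class difference. Defaults: correlation length 4.0 voxels
  (positive) vs 1.5 (negative), equal noise SD 0.25 — the shorter length
  makes the negative class the more heterogeneous, matching the direction of
  the reported texture finding, and keeps inter-voxel correlation alive at
  the GLCM displacement of 8 for the smoother class (autocorrelation ≈ 0.37
  at lag 8 for σ = 4, ≈ 0 for σ = 1.5);
* a homogeneous white-matter reference block (intensity 300 ± 1 arbitrary
  units) disjoint from the lesion, background at 240 ± 3, and an enhancing
  lesion baseline of 1.6× the white-matter signal.

What the generator does **not** model: anatomy, MR physics, scanner and
vendor heterogeneity (the clinical cohort spans three vendors and two field
strengths), partial-volume effects, infiltrative lesion margins, or any
true biological coupling between genotype and texture. Passing recovery
tests therefore show that the pipeline detects the class structure it is
pointed at — not that BRAF status is detectable at these effect sizes in
real scans. Lesion size is a free parameter because the reported size
statistic (19.62 ± 18.3 mm³) is implausibly small for resected metastases
and was not copied.

## Problem sizes in the shipped checks

The test suite and the acceptance script regenerate everything they measure:
GLCM oracle equivalence on random ≤ 12³ lesions over all 13 offsets and
distances 1–8; univariate type-I calibration on 1000 null features at
25 + 29 lesions; null-cohort calibration and texture-effect recovery on 10
replicate cohorts of 54 lesions each. These sizes give Monte-Carlo error
comfortably inside the asserted bands while keeping a full run in minutes.

## Known limitations

* The published headline numbers (accuracy 0.79 ± 0.13, AUC 0.78, 50/195
  significant features, 9 components) are properties of the original
  54-lesion clinical cohort, which is not public; they are not reproduction
  targets of this package.
* The per-fold "42 and 11 patients" split stated for the original 53-patient
  experiment cannot hold in all five folds; balanced sizes
  {11, 11, 11, 10, 10} are implemented.
* IBSI compliance is not claimed; gray-level quantization depth (32), GLCM
  symmetry and entropy base are declared conventions, not inferred intent.
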