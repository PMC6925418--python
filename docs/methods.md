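# Methods

This note documents the models, conventions and numerical choices behind
`voiradiomics`, and what the synthetic cohorts can and cannot establish.

## Synthetic cohort model

Each case is a 3D grayscale volume (default 64×64×28 voxels at
1×1×2 mm — thicker slices than in-plane, as in routine MRI) containing one
lesion on a homogeneous background with additive Gaussian noise
(`noise_sd`, default 1).

**Lesion geometry.** The mask is star-convex per axial slice: at slice z the
radial outline is `r_z · (1 + irregularity · f(θ, z))`, where `r_z` traces
an ellipsoidal through-plane profile (half-height ≈ in-plane radius in
physical units) and `f` is a unit-variance band-limited Fourier series
(4 angular modes) whose coefficients drift linearly across slices.  This
mimics slice-wise manual delineation: irregular but star-convex outlines
that vary smoothly from slice to slice, so the 3D mask is connected.  The
lesion center and base radius (default 7–11 voxels) are drawn uniformly,
keeping a margin of the maximum perturbed radius plus 7 voxels to the image
border so that even a radius-7 dilation never clips.

**Class contrast.** Lesion voxels are
`background + contrast·noise_sd + label·intensity_effect·noise_sd +
texture_sd·noise_sd·F`, where `F` is a zero-mean unit-variance Gaussian
random field obtained by Gaussian-smoothing white noise at correlation
length `base_correlation_length + label·texture_effect` voxels.
`intensity_effect` is therefore the class difference in mean lesion
intensity in noise-SD units (verified empirically in the tests), and
`texture_effect` the difference in texture correlation length in voxels.
With both effects zero the classes are exchangeable by construction.
Effect sizes are free parameters of the phantom, not estimates of any real
cohort.

**What the phantom does not model:** MRI physics (Rician noise, bias
fields, partial volume), multi-sequence acquisition, reader-specific
delineation styles, or class differences in lesion shape.  Passing
pipeline tests on these cohorts shows the machinery is correct and
well-calibrated, not that any particular clinical effect size is
attainable.

**Split.** Stratified per class at a configurable validation fraction
(default 0.25; 0.33 is the other conventional choice), assigned by a
dedicated RNG stream so the split never perturbs case content.

## Delineation variants

Erosion/dilation use the exact Euclidean disk `{(dx,dy): dx²+dy² ≤ r²}`
applied independently per axial slice (a flat-in-z structuring element), so
results are oracle-checkable: a single voxel dilated at r = 3 has exactly
29 pixels.  Toolboxes that default to octagonal disk approximations will
differ slightly.  Smoothing correlates each slice with a normalized 7×7
Gaussian kernel (σ = 3, replicate border) and re-binarizes at 0.5 — the
half-maximum contour — which makes a constant slice a fixed point; for a
symmetric kernel, correlation and convolution coincide.  Perturbations
touch masks only, never image voxels, and slices empty at baseline stay
empty.  Erosion that empties a mask is flagged explicitly
(`empty_after_perturbation`) and refused downstream.

## Feature extraction

The VOI is resampled to an isotropic grid (trilinear for the image;
linear-then-0.5-threshold for the mask) covering the mask bounding box with
a one-voxel pad anchored on the min corner voxel, then quantized to Ng gray
levels by one of: equal-width bins (`uniform`), quantile bins (`equal`), or
a Lloyd-Max scalar quantizer (centroid/boundary iteration, tolerance 1e-7,
max 500 iterations, initialized at equal-width centroids).  A constant VOI
quantizes to level 1 with a warning and all texture features take their
degenerate limits (never NaN): single-cell GLCM has energy 1, entropy 0,
contrast 0, correlation defined as 1; NGTDM coarseness is capped at 1e6
when its denominator vanishes.

Texture matrices follow the pooled-matrix convention: GLCM counts
distance-1 voxel pairs over the 13 unique 3D directions into one
symmetrized, normalized matrix (features are computed once on the pooled
matrix, not averaged per direction); GLRLM pools maximal equal-level runs
over the same 13 directions; GLSZM zones are 26-connected; NGTDM uses the
mean over valid 26-neighbors.  GLCM distance is fixed at 1.  The engine is
verified exactly against brute-force enumeration oracles on random small
volumes.

The 43-feature block is: Global (3) variance/skewness/kurtosis of the
100-bin in-mask intensity histogram (computed per combination from the
resampled VOI, so it varies with scale but not with quantization — the
duplication keeps every combination a uniform 43 features and realizes the
2064 textural total); GLCM (9); GLRLM (13); GLSZM (13) zone analogues;
NGTDM (5).  Run-length/size-zone gray-level and length variances are
probability-weighted variances of the level/length marginals.  The default
grid {1,2,3,4} mm × {equal, uniform, lloyd} × {8,16,32,64} gives
48 × 43 = 2064 texture features, plus 4 geometric features extracted once
from the native-resolution mask: volume (count × voxel volume), size (full
longest axis of the PCA inertia ellipsoid, `2·√(5·λ_max)` in mm),
solidity (mask voxels over voxelized convex-hull voxels, hull of voxel
centers; masks with < 4 non-coplanar voxels report 1 with a warning) and
eccentricity (`√(1 − λ_min/λ_max)`).

Intensity standardization is available as z-scoring over a body mask or a
simplified single-image landmark method (percentiles p1, deciles, p99
mapped piecewise-linearly onto [0, 100]); cohort-level landmark training
for multi-scanner harmonization is intentionally out of scope, and bias
field correction is assumed done upstream (synthetic images are bias-free).

## Robustness, selection and modeling

**ICC.** ICC(2,1) — two-way random effects, absolute agreement, single
measurement — with Baseline and one variant as the two raters; a systematic
shift therefore lowers robustness, which is the desired reading when the
"raters" are interchangeable delineations.  ICC(3,1) is available for
comparison.  Constant measurement vectors make the ICC undefined; such
features are excluded from robust counts and reported with an explicit
status rather than scored 0.

**mRMR.** Greedy MID criterion on mutual information (bits) with features
discretized to 3 levels at mean ± SD (inclusive boundaries, so binary
features land on the outer levels).  Ties break toward the earlier column,
making the ranking deterministic.

**0.632+ bootstrap AUC.** "63.2 % random data resampling" is implemented
literally as class-stratified subsampling without replacement of
⌈0.632·n⌉ per class (the classic with-replacement bootstrap, whose expected
unique fraction is the same 0.632, is available behind a flag).  The
selection-stage classifier is a ridge-regularized linear discriminant
(ridge 1e-3 of the mean covariance eigenvalue) — fast and deterministic;
the final model is always the random forest.  Stepwise ranking (default)
reuses one set of bootstrap splits across all candidates within a step
(common random numbers), so candidate comparisons are paired; univariate
ranking is the cheaper alternative used in the desk-scale runs.

**Models.** Incremental random forests (150 trees, scikit-learn defaults
otherwise, recorded via the seed in provenance) on the top-k features,
k = 1..20; the chosen k maximizes mean stratified 10-fold CV AUC with ties
resolved toward smaller k.  Cohorts too small for 10 folds reduce the fold
count with a warning.  Validation metrics: Mann-Whitney AUC (ties count
half), normal-approximation 95% CI from the DeLong placement-value
variance, and sensitivity/specificity/accuracy at probability 0.5 (a
training-set Youden threshold is available).  Model comparisons use the
DeLong test for correlated ROC curves; a vanishing variance of the AUC
difference (e.g. identical scores) reports p = 1 with a degenerate flag.
The transfer matrix applies each variant's fitted model (and feature
names) to validation tables extracted from every other variant.

## Desk-scale study sizes

Pipeline-level tests and the acceptance script run the study at reduced
size, chosen once: an 8-combination grid ({1,3} mm × {equal, uniform} ×
Ng {8,32}; 4 + 8×43 = 348 features), univariate 0.632+ ranking with 200
bootstrap replicates, cohorts of 30–50 subjects per class, and 5 seeds for
distributional claims.  The full 48-combination grid, stepwise ranking and
1000 replicates are the library defaults and only change runtime, not any
property asserted by the tests.  The feature-count check always uses the
full default grid.

With the spec'd validation fraction 0.25 and 30 subjects per class, the
validation set has 16 subjects; the null SD of the Mann-Whitney AUC at 8
vs 8 is √((n₀+n₁+1)/(12·n₀·n₁)) ≈ 0.149, so single-seed null AUCs scatter
widely around 0.5 — the calibration tests assert distributional bands, not
point values.

## Known limitations

- GLCM/GLRLM direction pooling and feature definitions follow one
  widely-used toolkit convention; IBSI-exact naming is not attempted (the
  name schema `family.feature.s<scale>.<algo>.g<Ng>` is documented above).
- The landmark normalization is a single-image stand-in; no cross-cohort
  landmark averaging.
- No stochastic contour randomization; perturbations are the five
  deterministic morphological variants.
- The resampling grid is anchored on the mask bounding box, so features are
  translation-invariant by whole voxels but not sub-voxel shift-invariant.
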