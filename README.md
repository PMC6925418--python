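# voiradiomics

How do differences in volume-of-interest (VOI) delineation propagate through
an MRI radiomics pipeline?  Radiomics models are built on features computed
inside a segmented lesion, but two readers (or one reader on two days) never
draw exactly the same contour.  `voiradiomics` implements, end to end, a
study design that answers this question with controlled perturbations:

1. **Delineation variants** — a baseline mask is perturbed slice by slice
   with morphological operations: erosion (disk radius 3 px), Gaussian
   smoothing (σ = 3 px, 7×7 window, replicate border, re-binarized at 0.5)
   and dilation (disk radii 3, 5, 7 px), giving the variants *Erosion,
   Smoothing, Dilation, Dilation5, Dilation7* next to *Baseline*.
2. **Feature extraction** — 2068 radiomics features per (image, VOI):
   4 geometric features (volume, size, solidity, eccentricity) plus 43
   texture features (Global histogram, GLCM, GLRLM, GLSZM, NGTDM) computed
   under 48 extraction-parameter combinations: isotropic voxel size
   {1, 2, 3, 4} mm × quantization {equal-frequency, uniform, Lloyd-Max} ×
   gray levels Ng {8, 16, 32, 64} (4 + 48 × 43 = 2068).
3. **Feature robustness** — per-feature ICC(2,1) (two-way random effects,
   absolute agreement) between each variant and Baseline across subjects;
   features with ICC ≥ 0.9 are counted as excellently robust.
4. **Feature selection** — mRMR (mutual-information MID criterion) shortlist
   of 100, then ranking by the 0.632+ bootstrap AUC
   (class-stratified 63.2 % resampling, AUC' = max(AUC_boot, 0.5),
   R = clip((AUC_app − AUC′)/(AUC_app − 0.5), 0, 1), w = 0.632/(1 − 0.368 R),
   estimate = (1 − w)·AUC_app + w·AUC′) down to the top 20.
5. **Modeling** — 20 incremental random-forest models (150 trees; top-k
   features, k = 1..20) compared by stratified 10-fold CV AUC; the best k is
   refitted and evaluated on an independent validation cohort (AUC with
   DeLong 95 % CI, sensitivity/specificity/accuracy, DeLong test vs the
   Baseline model) and across delineations (the variant × variant transfer
   AUC matrix).

Because the clinical cohorts such a study uses are private, the package
ships a **synthetic cohort generator**: two-class 3D lesion phantoms
(star-convex per-slice outlines, anisotropic voxel spacing, correlated
intra-lesion texture) whose classes differ in mean intensity and/or texture
correlation length at configurable effect size.  Every stage of the pipeline
is testable — down to exact brute-force oracles for the texture matrices —
without any data download.

## Worked example

```python
import voiradiomics as vr

# a 20-subject two-class cohort with a strong intensity effect
spec  = vr.CohortSpec(n_per_class=10, intensity_effect=4.0, seed=7,
                      validation_fraction=0.3)
cases = vr.generate_cohort(spec)

# one delineation variant and its volume change
d5 = vr.perturb_mask(cases[0].mask, vr.PerturbationSpec("dilate", 5))
print(round(vr.volume_ratio(d5, cases[0].mask), 3))     # 2.515

# the full 2068-feature vector for one case
fv = vr.extract_features(cases[0].image, cases[0].mask)
print(len(fv))                                           # 2068

# statsmodels-style model fit on a reduced grid (fast)
grid  = vr.ExtractionGrid(scales_mm=(1.0, 3.0),
                          quant_algorithms=("equal", "uniform"),
                          gray_levels=(8, 32))
table = vr.extract_cohort_table(cases, grid)
model = vr.RadiomicsModel.from_dataframe(
    table,
    selection=vr.SelectionConfig(n_bootstrap=100, ranking_mode="univariate",
                                 seed=8),
    spec=vr.ModelSpec(seed=9))
res = model.fit()
row = res.evaluate(table[table["split"] == "validation"])
print(res.chosen_k, round(row.auc, 3))                   # 1 0.889
```

The volume ratio 2.515 is the dilated-to-baseline voxel count for that
lesion; the fitted model keeps `chosen_k = 1` of the 20 ranked features
(cross-validation sees no gain from adding more when one intensity feature
carries the signal) and reaches AUC 0.889 on the 6 held-out validation
subjects — strong separation, as expected at a 4-noise-SD class difference
in mean lesion intensity.  (With 7 training subjects per class the model
warns that 10-fold CV is reduced to 7 folds.)

The whole study (simulate → perturb → extract → ICC → select → model →
evaluate → transfer → report) runs from the command line:

```bash
voiradiomics run-all --out-dir run1 --seed 3
cat run1/report/summary.md
```

or stage by stage (`simulate`, `perturb`, `extract`, `icc`, `evaluate`,
`validate`), each reusing artifacts already present in the run directory.

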