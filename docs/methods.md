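# Methods

`stsradiomics` implements an MRI-radiomics workflow for six-class
soft-tissue-tumor classification — five sarcoma subtypes (leiomyosarcoma,
myxofibrosarcoma, myxoid liposarcoma, dedifferentiated liposarcoma,
undifferentiated pleomorphic sarcoma) plus the benign mimic intramuscular
myxoma — from T1-weighted contrast-enhanced and T2-weighted fat-saturated
sequences.  This note documents the models, the synthetic data the package
is exercised on, and the numerical and design choices made where the design
was genuinely open.

## Feature extraction

Intensities inside the segmentation mask are rescaled relative to the
region statistics — the range `[mu - k*sigma, mu + k*sigma]` with `k = 3` —
and discretized into 32 equal-width, left-closed gray levels; values outside
the range clamp to the extreme bins.  A constant region (`sigma = 0`) maps
every voxel to bin 1; any constant assignment is equivalent for the texture
matrices.

Per volume the extractor produces 68 features:

| family      | count | notes                                               |
|-------------|-------|-----------------------------------------------------|
| shape       | 5     | volume (mL), surface area, compactness, sphericity, max 3D diameter |
| first-order | 12    | population moments, histogram entropy (bits), extremes, 5 percentiles |
| GLCM        | 6 × 5 | joint variance, autocorrelation, contrast, joint entropy, correlation, energy, at 1–5 mm |
| GLRLM       | 8     | run emphases, non-uniformities, run %, run entropy, gray-level emphases |
| GLSZM       | 8     | zone emphases, non-uniformities, zone %, zone size entropy, variances |
| NGTDM       | 5     | coarseness, contrast, busyness, complexity, strength |

Conventions: co-occurrence and run-length matrices accumulate over the 13
unique 3D directions and family features are averaged over directions;
zones and neighborhoods use 26-connectivity; all entropies use log base 2.
A spatial distance in mm converts to a voxel offset per axis as
`max(1, round(d / spacing_axis))` times the direction sign.  Surface area
comes from a marching-cubes mesh of the 0.5 isosurface; sphericity and
compactness use the mesh volume so both are bounded by 1 (isoperimetric
inequality), while the reported volume is voxel count × voxel volume.
Degenerate rules: GLCM correlation of a single-gray-level region is 1;
first-order skewness/kurtosis of a constant region are 0; NGTDM features of
a mask with no neighboring voxels are missing.  The extractor walks voxels
in Python for run/zone accumulation and is intended for ROI sizes up to a
few tens of thousands of voxels.

## Synthetic cohort

No image data accompany the workflow, so a generator emulates the
statistical structure the selection pipeline assumes.  Defaults mirror the
study cohort: 332 subjects split 67/55/60/33/70/47 across the six classes
and 1240 tagged feature columns, apportioned as evenly as possible over the
six sequence × plane blocks and within a block over the families by fixed
weights (GLCM gets half a block, cycled over the five distances).  The
planted structure is:

- **informative blocks** — disjoint column sets per class receive a
  Gaussian mean shift of `effect_size * noise_sd` (absolute `effect_size`
  in the noiseless limit) for that class's subjects; default 10 per class,
  effect size 1;
- **redundant pairs** — 50 near-duplicate pairs (`r >= 0.95`) planted among
  *non-informative* columns only, so "planted feature recovered" remains
  well defined under the correlation filter;
- **volume-linked columns** — 10% of columns follow
  `a + b * log(volume) + noise` with volumes log-normal (median ≈ 55 mL,
  sdlog 0.9), matching the imputer's regressor;
- **block missingness** — 15% of subjects lose one whole sequence, chosen
  uniformly between T1 and T2; a sequence block is always missing entirely
  or not at all.

What the generator does **not** emulate: scanner/protocol variation,
spatially structured feature correlations beyond the planted pairs,
non-Gaussian marginals, label noise, or anatomical site effects.  Passing
tests therefore demonstrate the pipeline's statistical machinery (ranking,
filtering, stability aggregation, calibration), not clinical performance on
real MRI.

Small 3D phantoms (sphere, box, checkerboard, two-level split) provide
analytically checkable inputs for the extractor.

## Missing-sequence imputation

Each feature is modeled as `value = intercept + slope * log(V) +
subtype_offset + subject_intercept + noise`, fit on the training partition
of each split only, and missing cells are filled from the fixed-effect
predictor.  Because the covariates are subject-level and plane replicates
are balanced under block missingness, the model has a closed-form ANOVA
solution: per-column fixed effects by least squares (one batched solve per
plane-replicate group) and the shared subject random-intercept variance
from the between/within decomposition of the group residuals.  Groups with
a single observation per subject fall back to ordinary least squares with
random-intercept variance 0.  Features with fewer than `p + 2` training
observations are flagged unfittable; an error is raised only if their
imputation is requested.

Using the subtype label at prediction time mirrors the source workflow but
leaks the classification target into imputed cells; the default therefore
logs a warning, and `use_subtype=False` gives a label-free, volume-only
imputer.  Volume enters as the natural log because radiomic features scale
multiplicatively with lesion size.

## Bootstrap selection

Each of `B` iterations (default 250): stratified 70/30 split
(largest-remainder per-class rounding), per-split train-only imputation,
then nested 5-fold cross-validation on the training partition.  Per outer
fold the features are ranked once by average gain of a gradient-boosted
tree ensemble; for each candidate size `N` the ranking is truncated to `N`
and greedily filtered for multicollinearity (drop a feature iff its
absolute Pearson correlation with an already-kept feature exceeds 0.90,
strict), and the surviving set is scored by macro one-vs-rest AUC on the
fold's validation part.  `N_opt` is the candidate with the best mean score
(ties to the smallest `N`); the final per-iteration set is the decorrelated
top-`N_opt` of a ranking refit on the whole training partition, and the
model refit on it is evaluated on the untouched 30%.

Default learner: 100 rounds, depth 3, learning rate 0.3,
`colsample_bytree = 0.3`, histogram method, single thread.  The strong
column subsampling is deliberate: without it the ensemble concentrates its
splits on one representative of each correlated informative block, the
remaining members receive zero gain, and the stability analysis
systematically starves them.  The default candidate grid spans 10–300 in
the documented steps; scaled-down experiments use grids sized to their
column count (e.g. {150, 200} for 600 columns).

Because decorrelation runs after truncation, the final set can be smaller
than `N_opt`.  Constant columns have undefined correlation and are kept.

## Robust signature

Per-iteration importances are assembled into a `B × F` matrix over the
union of selected features, with 0 for a feature a run did not select
(zero-fill; a selected-runs-only variant is available).  Per feature the
package reports selection frequency, mean/median/std importance (population
std — a single run must give std 0), PCA-weighted importance, and the
Combined Score = mean / std (signal-to-noise; std 0 with positive mean is a
+inf sentinel that passes the filter).

PCA weighting projects runs onto the first two principal components
(matching a 2-D consistency plot; configurable), measures each run's
Euclidean distance `d_i` to the projected centroid, and weights runs by
`w_i = 1 / (1 + d_i / median(d))`, normalized.  Median scaling makes the
kernel unit-free; all-identical runs give uniform weights and reduce the
weighted mean to the simple mean exactly.  Importances enter raw (not
per-run normalized).

The signature is the set with frequency > 0.80 **and** Combined Score > 1
(both strict), ordered by PCA-weighted importance.  An empty signature is a
warning plus an explicit empty result, never an error.

## Final model and evaluation

The signature features feed a single classifier evaluated by repeated
stratified 5-fold cross-validation (default 250 repetitions).  Within a
repetition every subject is predicted exactly once, out of fold; pooled
out-of-fold predictions give one confusion matrix and one ROC analysis per
repetition, and summaries are mean ± SD over repetitions (the
repetition-level convention is assumed and documented).  Global feature
attributions are exact tree Shapley values; additivity (attributions + base
= margin) is asserted to 1e-4 in tests.  Arms are compared pairwise with
the two-sided Wilcoxon signed-rank test, paired by iteration/repetition
index; zero differences are dropped, the statistic is `W+ − W−` (so
swapping arms flips its sign), and the p-value is exact for n ≤ 25 with
untied |differences|, otherwise a tie-corrected normal approximation.

ROC machinery: per-class one-vs-rest curves are interpolated onto a fixed
grid of 101 specificities (0.00–1.00) so curves aggregate point-wise across
iterations.  The interpolation evaluates the empirical ROC polyline: a grid
point hitting a vertical segment takes the segment's top (perfect
separation ⇒ sensitivity 1 everywhere, AUC 1), points between distinct
specificities interpolate linearly, and the AUC is the trapezoid over
1 − specificity.  Macro curves are unweighted means of interpolated
per-class sensitivities; micro curves pool all binary labels and scores
first.  Division-by-zero metric cells are NaN markers, never silent zeros.
Multiclass Cohen's kappa uses the marginal-product chance correction.

## Orchestration and problem sizes

The pipeline runs up to three arms — T1-only, T2-only, combined — from one
YAML config; a single master seed spawns per-(arm, stage) seeds through a
hash counter so any stage replays independently.  The final CV stage
requires a complete matrix, so the pipeline imputes the full table once
(imputer fit on all subjects) before that stage; the bootstrap stage keeps
strict per-split imputation.  The shipped desk-scale profile uses B = 25
and 25 repetitions on a 600-column cohort; the paper-faithful profile
(B = 250, 250 repetitions, 1240 columns) is configuration only.  The test
suite exercises the full B = 250 bookkeeping on a 60-subject, 60-feature
table and the signature-recovery property at 600 columns with B = 25 over
three master seeds.

## Known limitations

- Texture formulas follow common radiomics conventions but are not a
  numerical replication of any specific extraction software; anisotropic
  volumes are handled through the per-axis offset rule, without resampling.
- The imputer's subject random intercept is estimable only for
  plane-replicated features; singleton features silently use OLS.
- The generator's Gaussian, block-structured model is favorable to
  tree learners; real radiomic feature distributions are heavier-tailed and
  more entangled.
- Stability results depend on the learner actually using redundant
  informative features (see the column-subsampling note); markedly
  different learner settings can starve the frequency filter.
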