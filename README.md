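# stsradiomics

An MRI-radiomics pipeline for multi-class classification of soft-tissue
tumors.  The target problem: given pre-treatment T1-weighted
contrast-enhanced and T2-weighted fat-saturated MRI of a soft-tissue mass,
predict which of six histologic categories it belongs to — leiomyosarcoma
(LMS), myxofibrosarcoma (MFS), myxoid liposarcoma (mLPS), dedifferentiated
liposarcoma (ddLPS), undifferentiated pleomorphic sarcoma (UPS), or the
benign mimic intramuscular myxoma (MYX).  The package is aimed at
quantitative-imaging researchers who want a tested, reusable implementation
of the statistical machinery: 3D radiomic feature extraction, principled
handling of missing MRI sequences, and a resampling-based route to a small,
*stable* feature signature rather than a one-shot model.

## The method

1. **Feature extraction.** Within the tumor mask, intensities are rescaled
   to μ ± 3σ and discretized to 32 gray levels; shape, first-order, and
   GLCM / GLRLM / GLSZM / NGTDM texture features are computed in 3D, with
   GLCM features at spatial distances of 1–5 mm (68 features per volume,
   per sequence and imaging plane).
2. **Missing-sequence imputation.** Subjects missing a whole sequence have
   those features filled from a per-feature linear mixed model,
   `x = β₀ + β₁ log V + γ_subtype + b_subject + ε`, fit on the training
   partition of each split only (V = tumor volume; b = random intercept
   shared by plane replicates).
3. **Bootstrap-stable selection.** B = 250 iterations of: stratified 70/30
   split; nested 5-fold CV on the 70% choosing the feature-count *N*\_opt ∈
   [10, 300] by gain ranking + multicollinearity filtering (|r| > 0.90
   dropped) scored by macro one-vs-rest AUC; held-out evaluation on the 30%.
4. **Robust signature.** Per-feature selection frequency, mean / median /
   PCA-weighted importance and the Combined Score (mean importance ÷ its SD)
   are aggregated over the B runs; the signature keeps features with
   frequency > 80% and Combined Score > 1.
5. **Final model.** A classifier on the signature features evaluated by
   repeated stratified 5-fold CV (250 repetitions), with exact tree Shapley
   attributions and Wilcoxon signed-rank comparison of the T1-only /
   T2-only / combined arms.

Because no image data ship with the workflow, a first-class synthetic
cohort generator emulates the study structure (332 subjects, 67/55/60/33/
70/47 per class, 1240 tagged feature columns, planted informative blocks,
correlated redundant pairs, volume-linked features, block missingness) and
small 3D phantoms exercise the extractor against brute-force oracles.  See
`docs/methods.md` for the models, conventions, and limitations.

## Worked example

```python
import numpy as np
from stsradiomics import (CohortSpec, SelectionConfig, generate_cohort,
                          run_bootstrap, aggregate_importance,
                          apply_signature_filters)

spec = CohortSpec(n_features_total=600, n_informative_per_class=10,
                  effect_size=2.0, missing_fraction=0.15, n_redundant_pairs=30)
subjects, table = generate_cohort(spec, seed=11)

runs = run_bootstrap(table, subjects,
                     SelectionConfig(n_iterations=25, n_grid=(150, 200),
                                     master_seed=101))
sig = apply_signature_filters(aggregate_importance(runs))

planted = {f for fs in table.provenance["informative_by_class"].values() for f in fs}
print(f"signature size {len(sig.features)}")
print(f"mean held-out accuracy {np.mean([r.accuracy for r in runs]):.3f}")
print(f"mean held-out macro AUC {np.mean([r.macro_auc for r in runs]):.3f}")
print(f"planted-feature recovery {len(planted & set(sig.features))/len(planted):.3f}")
```

prints

```
signature size 49
mean held-out accuracy 0.992
mean held-out macro AUC 1.000
planted-feature recovery 0.817
```

i.e. from 600 columns (60 of them genuinely class-informative at effect
size 2) the stability + signal-to-noise filters distill a 49-feature
signature containing 49/60 of the planted features and no false positives,
while the bootstrap models discriminate the six classes nearly perfectly on
held-out splits at this effect size.

The same workflow is available from the shell:

```bash
stsradiomics simulate --seed 1 --out-dir cohort
stsradiomics run-all configs/desk.yaml   # three arms + comparisons + reports
stsradiomics extract vol.nii.gz mask.nii.gz --sequence T2 --out features.csv
```

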