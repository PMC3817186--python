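# dermcadx

Computer-aided diagnosis (CADx) of skin lesions from conventional digital
macrophotographs: given an RGB close-up photograph and a manually drawn
lesion border, the package classifies the lesion as benign or malignant and
quantifies how much each image feature contributes to that decision.

It is written for researchers in medical image analysis who want a complete,
reproducible reference pipeline for lesion classification on ordinary
(non-dermatoscopic) photographs — including the multidimensional color
features (inter-channel Pearson correlations and RGB principal-component
variances) that markedly improve discrimination over classical
single-channel color statistics.

## The method

Each photograph/border pair is reduced to a rectangular *sub-image* that
contains the lesion centered plus an equal pixel-area of surrounding normal
skin, and a feature vector **x** ∈ ℝ⁹¹ is extracted:

* **Shape (3)** — from the binary mask: asymmetry (principal-axis reflection
  mismatch), compactness P²/(4πA), and radial variance Var(d)/E[d]² of
  centroid–boundary distances.
* **Texture (46)** — 11 gray-level run-length matrix statistics (SRE, LRE,
  GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE), averaged over the
  0°/45°/90°/135° scan directions, at 16/8/4/2 gray levels; plus Tamura
  coarseness of the sub-image and of the lesion area alone.
* **Color, single-channel (24)** — variance, Shannon entropy and skewness of
  the gray/R/G/B values, over the sub-image and over the lesion alone.
* **Color, multidimensional (18, the "new" set)** — the six Pearson
  correlations r(R,G), r(G,B), r(B,R), r(R,gray), r(G,gray), r(B,gray), and
  the eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of the 3×3 RGB covariance matrix (PC1–PC3
  color variances), each for both regions.

Features are ranked by recursive feature elimination with a linear
soft-margin SVM (at each step, refit, drop the feature with the smallest
wⱼ²), and classifiers built from the top-*n* sets are evaluated by
leave-one-out cross-validation: the pooled held-out decision scores give a
ROC curve and its area Az = P(score_malignant > score_benign). Two nested
feature sets — the 73 "conventional" features versus all 91 — are compared
on the same records with DeLong's test and a paired bootstrap t-test on Az.
Clinical count tables (correct/incorrect diagnoses per histological
category) yield sensitivity, specificity and accuracy with Wilson 95%
intervals.

Because no public image set exists for this task, the package ships a seeded
synthetic generator: star-convex lesions r(θ) = r₀(1 + Σₖ aₖ sin(kθ+φₖ)) on
skin-colored background, with benign lesions unimodal in color and nearly
smooth, and malignant lesions drawing from a spatially clustered multi-color
mixture with a more irregular border.

## Worked example

```python
import dermcadx as dc
from dermcadx.synthetic import malignant_config
from dermcadx.features import NEW_FEATURES

# one synthetic malignant macrograph -> 91 features
image, mask, label = dc.generate_lesion_image(malignant_config(), seed=7)
pair = dc.make_region_pair(image, mask)
f = dc.extract_features(pair)
print(f"{f['shape.compactness']:.4f}  {f['color.pca.pc3.lesion']:.4f}")
# 1.1894  69.6993
#   compactness 1.19: mildly irregular border (a perfect disk scores ~1)
#   lesion PC3 69.7: genuinely 3-D color cloud (a single-tone nevus is ~0)

# baseline-vs-proposed comparison on a table whose signal lives only in
# the new multidimensional color features
table = dc.generate_feature_table(
    60, 60, seed=1, mode="direct",
    informative_features=list(NEW_FEATURES[:5]), effect_size=1.5)
report = dc.compare_feature_sets(table, max_features=10, bootstrap_b=500, seed=1)
c = report["comparison"]
print(f"Az {c['az_baseline']:.3f} -> {c['az_proposed']:.3f}, DeLong p = {c['delong_p']:.2g}")
# Az 0.749 -> 1.000, DeLong p = 1.3e-08
```

The 73-feature baseline cannot see the planted correlation/PCA signal and
hovers near chance-plus-overfit; adding the 18 multidimensional color
features lifts the leave-one-out Az to 1.0, and DeLong's test confirms the
improvement.

A command-line interface mirrors the library:

```sh
dermcadx simulate --mode rendered --n-benign 10 --n-malignant 10 --seed 0 --out features.csv
dermcadx evaluate features.csv --outdir run1 --compare-baseline --seed 0
dermcadx extract manifest.csv --out features.csv     # your own images + masks
dermcadx clinical-stats                               # packaged count table
dermcadx fixtures --outdir fx                         # analytic test images
```

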