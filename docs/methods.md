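# Methods

This note records the model, the numerical conventions, and the design
choices that were genuinely open, in enough detail to reimplement the
package or to swap a convention deliberately.

## Regions of analysis

All features are computed on one or both of two pixel populations derived
from a photograph and its manually drawn lesion border: the **lesion
region** (pixels under the mask) and the **sub-image** (a rectangle holding
the whole lesion, centered on the lesion centroid, containing in addition an
equal pixel-count of surrounding normal skin). Equalizing the skin and
lesion areas standardizes how much skin context enters statistics that mix
the two populations, without attempting photometric calibration.

The rectangle construction is deterministic: take the aspect ratio of the
lesion bounding box, target an area of twice the lesion pixel count, and
search side lengths within ±6 px of the ideal (subject to containing the
lesion with a 1-px margin), preferring candidates that meet
`|skin − lesion| ≤ 0.02·lesion`, then minimal aspect deviation, then
minimal area deviation. Rectangles cut by the photograph border carry a
`clipped` flag; when the 2% balance is unreachable (tiny lesions whose
area admits no suitable integer factorization, or heavy clipping) the best
available rectangle is returned with `tolerance_met=False` rather than
failing the whole record. Lesions so large that less than half their area
of skin remains in the frame are rejected outright.

Grayscale is BT.601 luma (0.299 R + 0.587 G + 0.114 B), kept real-valued.
Gray-level reduction to L ∈ {2, 4, 8, 16} uses uniform bins on [0, 256):
q = ⌊g·L/256⌋ clamped to L−1, so the bin boundary at 256/L sits exactly
between 8-bit codes.

## Shape features

* **Compactness** P²/(4πA): A is the lesion pixel count; P is the length of
  the Moore-neighbor boundary tour with Vossepoel–Smeulders step weights
  (0.980 per axis step, 1.406 per diagonal step). The naive 1/√2 weighting
  overestimates smooth digital contours by ≈5%, which visibly inflates a
  disk's ratio above 1; the corrected weights bring a radius-30 disk to
  ≈1.03 while a 40×40 square stays within 10% of its continuous value
  16/(4π) ≈ 1.27.
* **Asymmetry**: principal axes come from the eigenvectors of the
  second-order central moments of the pixel coordinates. For each axis the
  mask is reflected across the line through the centroid and compared with
  itself; the reflection is evaluated by *inverse mapping* (each grid pixel
  samples the mask at its mirrored coordinate, rounded to nearest
  neighbor). Forward mapping of the pixel set loses pixels to rounding
  collisions at oblique axes and can score a symmetric shape as ~0.08;
  inverse mapping keeps it ≤ 0.03. The score is |M Δ R|/(2A), averaged over
  the two axes (mean rather than min/max — recorded so alternates can be
  swapped), so it lies in [0, 1] with 0 for exact mirror symmetry.
* **Radial variance**: the squared coefficient of variation Var(d)/E[d]² of
  distances from the centroid to the (unique) boundary pixels of the Moore
  tour. Normalizing by the squared mean makes it dimensionless and
  scale-free.

Degenerate masks (single pixel, collinear pixels, fewer than 8 boundary
pixels) raise a dedicated error rather than returning a number.

## Texture features

**GLRLM.** Run-length matrices count maximal same-level runs per (level,
length) along each of the four standard directions; scan lines for 45° are
anti-diagonals traversed upward. The 11 statistics are the canonical set —
five Galloway (SRE, LRE, GLN, RLN, RP), two Chu (LGRE, HGRE), four
Dasarathy–Holder joint statistics — with gray levels used 1-based (g+1) in
the low/high-gray weightings to avoid division by zero at level 0. Each
statistic is the mean over the four directions (44 = 4 levels × 11
statistics per feature vector). Matrices are computed on the rectangular
sub-image only; run-length counting is not defined on a ragged lesion
region.

**Tamura coarseness.** For each scale k = 1..5, mean gray values over
2ᵏ×2ᵏ windows are differenced between adjacent non-overlapping windows
horizontally and vertically; each pixel takes S = 2ᵏ* for the scale with the
largest contrast, and coarseness is the mean S over all pixels whose
windows at every scale lie fully inside the image. Two conventions matter
and are deliberate:

* *Tie-breaking*: ties at positive contrast go to the **largest** window;
  zero-contrast pixels fall back to the smallest (S = 2). On sharp-edged
  textures every window size saturates simultaneously (on period-2b
  stripes, the contrast at window b/2 equals the contrast at window b
  wherever either is nonzero), so a smallest-k rule would collapse all
  checkerboards to coarseness 2.0 and destroy the monotone response to
  texture scale. A constant image still scores 2.
* *Scale truncation*: when 2^(k+1) ≥ min(H, W) the scale range is truncated
  (with a warning) so the evaluation set cannot be empty on the ~60–80 px
  sub-images the generator produces; an image with no valid pixel at all is
  an error.

The lesion-only coarseness averages S over lesion pixels but lets windows
straddle the border — excluding straddling windows would empty small
lesions. Note that square windows dilute full-block contrast in 2-D, so a
b-pixel checkerboard scores below b (≈2.7 for b = 4); the implementation is
tested against a direct per-pixel loop implementation rather than against
the folk "coarseness ≈ block size" heuristic.

## Color features

All moments are population moments — the pixel set *is* the population of
its region — and PCA is performed on raw 0–255 values (no standardization),
so the three eigenvalues of the RGB covariance matrix are the variances of
the color cloud along its principal axes and satisfy
λ₁+λ₂+λ₃ = Var(R)+Var(G)+Var(B) to 1e-9 relative on every input. Entropy
uses the raw 256-bin integer histogram, log base 2, 0·log 0 = 0; skewness is
m₃/m₂^1.5 with the constant-sample case defined as 0. A Pearson correlation
with a constant argument is undefined; it maps to 0 with a degeneracy flag
so feature tables stay rectangular (synthetic noiseless fixtures hit this
case routinely).

## Selection and classification

Columns are z-scored (population SD; constant columns flagged and left at
spread 1) inside **every** fit — squared-weight ranking across features with
wildly different natural scales is meaningless otherwise, and refitting the
scaler inside each LOOCV fold keeps the held-out record out of the scaling.
The classifier is an L2-regularized linear SVM with squared hinge loss,
solved in the primal (deterministic; tolerance 1e-10), cost C = 1 by
default with no class weighting. RFE removes exactly one feature per
iteration — the smallest w² — with ties broken by removing the
lexicographically last name, so rankings are bit-reproducible.

## Evaluation

Az is computed exactly by midranks (ties count ½) and equals the
trapezoidal ROC area. ROC operating points are enumerated at midpoints
between consecutive distinct scores plus ±∞ sentinels, with
`score ≥ threshold ⇒ malignant`; the max-accuracy point breaks ties toward
higher specificity, then higher threshold. DeLong's test uses the
structural-components covariance on paired scores (sample covariance,
ddof 1); a zero-variance difference with equal Az returns p = 1, with
unequal Az it raises. The paired bootstrap resamples records with
replacement (replicates that lose a class are redrawn, at most 100 times),
and tests the Az difference with the studentized pivot
t = mean(d*)/sd(d*), df = B−1 — *not* a one-sample t-test over B
replicates, which would shrink the standard error by √B and reject
essentially every null dataset. Measured type-I error at the 5% level over
100 null datasets (B = 500) falls within binomial bounds [1%, 11%].

Clinical confidence intervals are Wilson score intervals; for 145/174 the
Wilson interval is 77.09–88.14%, matching the published interval for that
count to 0.01 percentage points. Univariate screening Az is orientation-free
(max(A, 1−A)) so single-feature values lie in [0.5, 1]. The default cap of
16 features in the top-*n* sweep follows the rule of keeping the model
smaller than one tenth of the number of malignant cases at the 174-case
scale; it is a configuration default, not a hard limit.

## Synthetic data: what it emulates, and what it does not

The rendered tier emulates the imaging conventions the pipeline assumes —
one centered lesion, ≤ 50% of the frame, skin context on all sides — plus
the two class contrasts the classifier exploits: color dispersion (benign:
one palette color, default (120, 80, 60), spread 8; malignant: three
spatially clustered palette colors {(90, 60, 50), (60, 70, 80),
(150, 60, 60)}) and border irregularity (radial perturbation amplitude 0.04
benign vs 0.12 malignant over harmonics 2–5). Defaults: 128×128 frame,
lesion radius 18–28 px, skin (200, 170, 150) with spread 3, per-channel
noise SD 2. The palettes are fixed and documented but **non-clinical**: no
photometric realism, hair, specular reflection, shadowing or camera noise
model is attempted. Star-convex boundaries were chosen over free-form blobs
because the continuous polar curve is available in closed form for
shape-feature oracles. Consequently, passing tests demonstrate that the
pipeline recovers the intended statistical structure from images with that
structure — not that the features transfer to clinical photographs.

The direct tier skips rendering and samples the 91 named columns from two
unit-variance Gaussians, shifting a configurable informative subset by a
given effect size. It exists because selection/evaluation behavior (RFE
recovery, null calibration, baseline-vs-proposed contrast) is cleanest to
test when ground truth is exact and generation is instant.

## Problem sizes

The test suite and the acceptance script run everything at desk scale,
chosen as the smallest sizes at which each statistical claim is stable:
oracle equivalence on 200 random 8×8 images; RFE recovery over 20 seeds at
n = 120 with 8 noise columns; the planted-signal contrast at n = 120 with
effect size 1.5 on five new-color columns and a 10-feature cap; null
calibration as a 5-seed mean at n = 60 (a single null LOOCV Az at n = 60
has SD ≈ 0.09–0.12, so single-seed assertions against a ±0.15 band would
fail a nontrivial fraction of correct implementations); bootstrap
calibration with B = 500 over 100 datasets.

## Known limitations

* The equal-area rectangle is a convention; the construction is not unique
  and other centered rectangles satisfying the 2% balance exist.
* Tamura coarseness depends on the window/tie conventions above; absolute
  values are not comparable across implementations with different
  conventions (ordering by texture scale is).
* The clinical count statistics operate on printed aggregate counts only;
  nothing in the package re-derives the underlying image classifications.
* LOOCV Az on heavily over-parameterized tables (p ≫ n) is noisy and can
  sit well away from 0.5 under the null for a single dataset; conclusions
  should rest on multiple seeds, as the acceptance checks do.
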