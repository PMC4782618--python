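# Methods

## Synthetic H&E scene model

Each scene is a flat eosin-pink cytoplasm field (RGB ≈ (235, 170, 200))
with non-overlapping hematoxylin-blue nuclei (RGB ≈ (70, 50, 150)) on a
160×160 px canvas.  Per nucleus: the mean radius is drawn from a
log-normal (strictly positive and parameterized directly by a
coefficient of variation), an area-preserving aspect ratio and a uniform
orientation give an ellipse, and the boundary radius is modulated by one
low-order sinusoid r(θ) = 1 + A·sin(hθ + φ), h ∈ {2, 3, 4}, amplitude
A = `boundary_irregularity`.  Nuclei are placed by rejection sampling
(≤ 500 retries, largest first — resolving the tightest constraint in an
empty scene makes placement reliable; non-overlap keeps per-nucleus
ground truth unambiguous for the shape descriptors).  A smooth zero-mean
"chromatin mottle" field (Gaussian-filtered white noise, σ = 2 px,
rescaled to `chromatin_mottle_sd`) is added to nucleus pixels on all
channels, then i.i.d. Gaussian color noise (default SD 12) is added
everywhere and the image is clipped to 8 bits.  One seeded generator
stream per scene; every output is a pure function of the spec.

Class constants (documented stand-ins — the qualitative contrasts are
textbook histopathology, the numbers are synthetic choices):

| parameter | normal | cancerous |
|---|---|---|
| nucleus radius mean (px) | 7 | 10 |
| radius CV | 0.08 | 0.30 |
| boundary irregularity | 0.05 | 0.30 |
| chromatin mottle SD (intensity) | 2 | 12 |
| nuclei per scene (uniform) | 9–11 | 6–10 |

The cancerous count range is wider, so cellularity varies more between
cancerous scenes.  Measured over 100 scenes/class, mean per-scene
nucleus area separates the classes by ≈ 3 pooled SDs and the per-scene
SD of nucleus areas by ≈ 2.6; the chromatin mottle separates in-ROI GLCM
contrast by ≈ 6.  The mottle amplitude is capped at 12 so that, under
k = 3 color clustering, the within-cluster variance of the (larger)
cytoplasm cluster still exceeds the mottled nucleus cluster's and
k-means splits the background, not the nucleus.

What the generator does **not** emulate: overlapping/touching cells,
stain variation and uneven illumination, tissue-type-specific texture
(connective vs epithelial vs muscular vs nervous), out-of-focus blur.
Passing tests therefore demonstrate that the pipeline's plumbing
preserves a morphology signal it is pointed at — not performance on real
biopsies.

## CLAHE

Tiles (default 8×8 grid) get per-tile histograms (256 bins) clipped at
`clip_limit × tile_pixels` (default 0.01 of the tile mass; ∞ disables
clipping) with the excess redistributed uniformly in a single pass (no
iterative re-clipping; the mapping may exceed the nominal clip slightly,
which is the standard fast variant).  The mapping is the classic
normalized-CDF transform m(v) = round((cdf(v) − cdf_min)/(N − cdf_min)
× 255); per-pixel output interpolates bilinearly between the four
surrounding tile-center mappings, clamped at the borders.  With one tile
and no clipping this is exactly global histogram equalization, which the
tests verify against a direct CDF oracle.  A fully degenerate tile
(all mass in one bin after no clipping) maps by identity, so constant
images stay constant.  RGB images are equalized on the luminance of a
full-range YCbCr decomposition with chroma untouched — hue-preserving by
construction, which protects the downstream HSV color features; a
per-channel flag exists for comparison.  CLAHE is not idempotent.

## Segmentation

Lloyd's k-means on per-pixel color vectors (RGB, or CIE L\*a\*b\* for
the "color k-means" variant), squared Euclidean assignment,
initialization by seeded choice of k distinct pixel colors, ≤ 300
iterations, convergence on stable assignments.  An emptied cluster is
re-seeded at the point farthest from its assigned center, keeping k
fixed.  Labels are canonicalized by descending cluster size so a given
(image, k, seed) yields the identical mask.  Fuzzy c-means uses the
standard alternating updates (fuzzifier m = 2, tolerance 1e−5 on center
movement); zero-distance pixels get crisp membership.  The nucleus ROI
is selected by rule: `most_blue` (mean B − (mean R + mean G)/2 maximal —
hematoxylin), `darkest` (minimum mean luminance), or an explicit index.
k = 3 is the default cluster count for the biopsy pipeline.

## Segmentation evaluation

Pixel confusion rates (accuracy, sensitivity, specificity, FPR) on
binary masks; PRI, VOI and GCE on arbitrary label rasters via the joint
contingency table (O(pixels + labels²)), which the tests pin to
exhaustive pair-loop / set-difference oracles on all partition pairs of
small images.  VOI uses natural logarithms (nats).  GCE is the
symmetric Martin form min of the two directional refinement-error sums;
it is 0 whenever one partition refines the other.  Ratios with zero
denominators are reported as NaN with an explicit `undefined` flag,
never silently zeroed.

## Feature bank (115 values)

Families and regions (the grayscale channel is the BT.601 luminance of
the enhanced RGB):

* **GLCM texture (22)** — on the nucleus ROI; 32 gray levels, offsets
  {(0,1), (1,0), (1,1), (1,−1)}, each symmetrized and normalized, then
  averaged.  Statistics are the extended Haralick set with 1-based level
  indices and base-2 entropies (0·log 0 = 0).  The set contains two
  textbook correlation formulations; for a symmetric normalized GLCM
  they coincide, which keeps the canonical 22-slot layout.
* **Shape (10)** — on the ROI's largest connected component: area,
  chain-code perimeter (axis steps + √2·diagonal steps, Moore boundary
  tracing with Jacob's stopping criterion; a single pixel has perimeter
  1), moment-based major/minor axis lengths with the +1/12 pixel-extent
  correction (a 1-px-wide bar gets a finite ≈1 px minor axis),
  equivalent diameter, orientation (degrees), convex area, filled area,
  solidity, and eccentricity as the major/minor length ratio (≥ 1 — the
  morphology-literature convention, not the ellipse eccentricity).
* **HOG (36)** — ROI bounding box resized to 64×64, centered-difference
  gradients, 9 unsigned orientation bins, 2×2 cells of 32×32 px, one
  L2-normalized block; a constant patch maps to the zero vector.
* **Wavelet (32)** — two single-level Daubechies-4 DWTs (periodization,
  so Parseval holds exactly); 8 subbands × {mean |c|, entropy of the
  normalized |c| distribution, energy, sum}.  Subbands whose largest
  coefficient is below 1e−8 are treated as exactly zero so round-off
  noise cannot masquerade as entropy.
* **Color (6)** — HSV means and population SDs over ROI pixels.
* **Tamura (3)** — whole image.  Coarseness: best-responding window
  size 2^k, k = 1..5, per pixel, averaging 2^k*; responses below 10 % of
  the image's maximum response are discarded as filter-alignment residue
  (otherwise near-zero large-window responses capture pixels and bias
  the estimate upward).  Contrast: σ / kurtosis^¼ (0 for constant
  images).  Directionality: 1 minus the normalized mean squared wrapped
  distance from the peak of a 16-bin gradient-orientation histogram
  (magnitudes below the 10th percentile excluded) — ≈ 1 for a single
  stripe orientation, ≈ 0 for isotropic noise.
* **Laws texture energy (6)** — whole image, local mean (15×15) removed;
  5×5 masks from L5/E5/S5/R5 vectors; energy = image mean of the 15×15
  moving average of |response|; transpose pairs averaged: L5E5, L5S5,
  E5S5, E5E5, S5S5, R5R5.

The schema (names `F001_autocorrelation` … `F115_lte_r5r5`) is fixed and
versioned; `extract_all` always returns exactly 115 finite values or
raises with the failing family named.  Per-nucleus descriptors
(area, brightness, NLD/NSD, elongation = NSD/NLD, perimeter,
roundness, solidity, eccentricity = NLD/NSD, compactness = A/P²) are a
separate API and not part of the 115-vector, whose family widths are
fixed by the schema.

## Classification

Features are z-scored with training-set statistics (zero-variance
columns dropped); mixed units (pixel areas next to entropies) make raw
Euclidean distances meaningless otherwise.  KNN uses k = 5, stable
distance sort (distance ties resolve to the lowest training index) and
the "nearest" rule for vote ties.  Fuzzy KNN is Keller's algorithm with
crisp training memberships and inverse-distance weights d^(−2/(m−1)),
m = 2; a query coinciding with a training point inherits its label with
membership 1; memberships are clipped to [0, 1] against float overshoot
and sum to 1 per query.  SVM (linear kernel) and random forest
(500 trees, 10 candidate features per split, seeded) are scikit-learn
adapters behind the same fit/predict contract.  Cross-validation is
stratified 10-fold (shuffled, seeded); standardization is re-fit on each
training fold (no leakage); single-class test folds are flagged.  Both
pooled (summed confusion counts) and fold-averaged metrics are reported;
fold-averaged is the primary summary.  Accuracy is carried on both the
percent and fraction scales to avoid unit bugs.

## Pipeline and reproducibility

`run_pipeline` executes simulate → enhance → segment → features → train,
writing every intermediate artifact under the run directory together
with the config, its SHA-256 hash and the package version.  A single
master seed derives per-stage (and per-image) seeds by stable CRC-32
mixing, all below 2³¹.  Repeat runs are byte-identical, which the test
suite asserts on `features.csv` and `report.json`.

## Problem sizes used in checks

Exhaustive metric oracles run on all partition pairs of 5-element
images (Bell(5)² = 2704 pairs) plus 100 random 8×8 label pairs at
1e−12 tolerance; a 2¹²-assignment brute force pins the k-means optimum
on 12 pixels.  Segmentation recovery is measured on 20 seeded scenes and
the end-to-end classification benchmark on 100 scenes per class (full
pipeline, ~30 s total); class-separation checks use 100 scenes per
class.  These sizes give stable statistics for a property-based suite
while keeping a full run interactive.

## Known limitations

* The synthetic classes are deliberately well separated; near-perfect
  CV accuracy on them validates the chain, not clinical performance.
* `most_blue` ROI selection assumes H&E-like color contrast; other
  stains need the `darkest` or `by_index` rules.
* The chain-code perimeter overestimates smooth contours by a few
  percent (digital-geometry bias), so roundness of a rasterized disk is
  ≈ 0.95, not 1.0.
* Touching or overlapping nuclei are out of scope by construction; the
  per-nucleus descriptors assume the generator's disjoint ground truth
  or a prior instance segmentation.
* Tamura coarseness/directionality follow common operationalizations of
  the original perceptual definitions (choices documented above);
  absolute values are not comparable across other implementations,
  though orderings are.
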