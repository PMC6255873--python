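# Methods

## Problem and approach

The tumor proportion score (TPS) of a PD-L1 immunohistochemistry (IHC)
slide is the percentage of tumor cells with membrane staining; under the
Ventana SP263 assay a patient is called PD-L1 positive when TPS ≥ 25%.
`pdl1tps` reproduces an automated scoring pipeline for this readout:

1. **Tissue detection** separates stained tissue from slide background.
2. **Patch classification** assigns small image windows to one of eight
   region classes — PD-L1 positive/negative tumor cells (TC+ / TC−),
   positive/negative lymphocytes, macrophages, necrosis, stroma and
   non-tissue — using a classifier trained semi-supervised with an
   auxiliary-classifier GAN (AC-GAN).
3. **Sliding-window inference** produces per-pixel class posteriors over
   the tissue, each pixel taking the class of maximum probability.
4. **Scoring** computes `TPS = 100 · #TC+ / (#TC+ + #TC−)` from pixel
   counts; every other class is excluded from numerator and denominator.
   A slide with no detected tumor pixels has an *undefined* TPS (flagged,
   never reported as 0).
5. **Concordance evaluation** compares the automated score with visual
   scores: Lin's concordance coefficient (Lcc), Pearson correlation (Pcc),
   mean absolute error (MAE), and overall/negative/positive percent
   agreement (OPA/NPA/PPA) of the dichotomized status at the 25% cut-off,
   plus analyses stratified by inter-rater variability.

## The AC-GAN semi-supervised classifier

A generator `G(c, z)` maps a 100-dimensional standard-normal noise vector
`z` concatenated with a one-hot class condition `c` to a fake patch.  A
discriminator `D` shares one spectral-normalized convolutional trunk
between a source head `P(S = real | X)` and an auxiliary class head
`P(C | X)`.  With natural logarithms and expectations over the batch,

    L_S = E[log P(S=real | X_real)] + E[log P(S=fake | X_fake)]
    L_C = E[log P(C=c  | X_real)]  + E[log P(C=c  | X_fake)],

`D` ascends `L_C + L_S` and `G` descends `L_S − L_C`, alternating one
update each per iteration (the update ratio is a free choice; 1:1 is
used).  The real-data term of `L_C` runs over *labeled* patches only;
unlabeled patches still shape the shared trunk through `L_S`.  This is
what lets unannotated tissue improve the classifier.

Training batches contain 64 labeled patches (fully-supervised baselines)
or 32 labeled + 32 unlabeled patches (semi-supervised modes); the fake
batch matches the real batch size.  All models use Adam with
`lr = 1e-4, β₁ = 0.5, β₂ = 0.999`.  Model selection keeps the checkpoint
maximizing top-1 accuracy on a held-out labeled set, evaluated every
`eval_every` (default 100) iterations; the saved checkpoint includes
batch-norm statistics and spectral-norm state so re-evaluation reproduces
the recorded accuracy exactly.

Baselines: a plain batch-normalized CNN classifier (fully supervised,
cross-entropy), and a convolutional autoencoder sharing the classifier
trunk, trained with reconstruction loss on the complete batch plus
classification loss on the labeled patches (weighted 1:1, a free choice).

### Numerical choices

- Probabilities are clipped to `[1e-7, 1 − 1e-7]` before logarithms, so a
  perfect discriminator yields `L_S ≈ 0` within `2ε` rather than −∞.
- Spectral normalization uses one warm-started power iteration per
  training forward pass; the backward pass propagates through
  σ = uᵀWv with u, v held fixed, i.e. the gradient of W/σ carries the
  standard rank-1 correction −(ΣG⊙W̄)/σ · uvᵀ on top of G/σ.  The
  standalone `spectral_normalize` routine iterates to convergence
  (relative tolerance 1e-12, cap 5000 sweeps) and agrees with a full SVD
  to better than 1e-3.
- Class-probability argmax ties break toward the lowest class ID.
- Overlapping sliding windows are aggregated by arithmetic mean of
  posteriors; a final window row/column is added flush with the image
  edge so every tissue pixel is covered.
- The whole network stack is NumPy (im2col/col2im convolutions, manual
  backward passes) in float32; every layer's gradients are verified
  against central finite differences in float64 in the test suite.

### Network engine

No deep-learning framework is part of the dependency set; the package
ships a compact NumPy engine (`pdl1tps.nn`) providing exactly the layers
the models need: dense, strided convolution, transposed convolution
(including a fast non-overlapping k = stride path used by the generator),
batch normalization, leaky-ReLU/ReLU/tanh, Adam, and spectral
normalization.  Architectures are configurable in depth/width; the
desk-scale defaults are a 3-block trunk at width 16 for 32×32 patches.
The clinical-scale geometry (128×128 patches, wider networks, 100k–200k
iterations) is reachable through the same configuration surface but is
not the test target.

## Tissue detection

Otsu's threshold is applied to a "whiteness" channel `(1 − S) · V` (HSV
saturation and value), which separates pale unsaturated background from
any stain hue; the binary mask is closed with a 5 px disk and components
smaller than 1000 px are removed (kernel sizes are free choices at the
working resolution).  A constant image has no Otsu threshold and returns
an empty mask with a warning.

## Patch sampling

Labeled patches are sampled on a 20 px grid anchored at the bounding box
of each connected annotated region, restricted to the *concordant* region
of two annotators (pixels where both assign the same class; everything
else is discarded).  A window is kept only when one label covers ≥ 90% of
the window — windows dominated by discarded or foreign pixels are
skipped, keeping labels clean near region borders.  Unlabeled patches sit
on a 60 px grid (full scale; desk-scale configs use denser grids since
synthetic slides are ~10× smaller than clinical scans) over detected
tissue, one patch per node whose center is tissue.  Labeled patches are
augmented with the full 4-fold rotation group.  Coordinates are 0-based
(x, y) = (column, row) with half-open extents; per-axis patch counts obey
`floor((L − patch)/stride) + 1`.

## Synthetic study generator

No clinical cohort is available, so the generator emulates the
*statistical* structure the pipeline depends on:

- **Palette** (mean RGB, noise SD, correlation length in px): DAB-brown
  for PD-L1-positive classes, hematoxylin-blue for negative classes, pale
  pink for stroma/necrosis, near-white background.  **Macrophages share
  the positive-tumor mean color and noise SD exactly** and differ only in
  texture correlation length (6 px smooth blotches vs 1 px granular
  stain), preserving the hardest confusion pair of the real task: color
  statistics cannot separate them, texture can.
- **Geometry**: class regions are carved from smoothed Gaussian random
  fields (blob scale `blob_sigma`, default 24–36 px), so regions are
  blob-shaped and spatially intermixed; realized areal fractions match
  the requested ones to rounding error.  `true_tps` is always computed
  from the realized label mask.
- **Raters**: visual scores are truth plus clipped Gaussian noise on the
  percentage scale (default SD 5 points, three raters — a simple model
  sufficient to exercise Δ and restricted-concordance machinery).  A
  second annotator's mask is simulated by relabeling a controlled
  fraction of pixels to a uniformly random different class.

Everything is bit-reproducible under a fixed seed.  What the generator
does **not** model: nuclei and cell morphology, stain variability and
batch effects, scanner artifacts, pen marks, tissue folds, continuous
staining intensity.  Passing tests therefore demonstrate the pipeline's
correctness and its semi-supervised machinery on data with the stated
structure — not clinical performance.

## Oracle classifier

End-to-end recovery tests need a known-good region detector independent
of training.  The `OracleClassifier` has privileged access to the palette:
each window pixel votes for its nearest palette mean color (the two brown
classes pooled), and brown pixels are then split by the local luminance
standard deviation at two scales (9 px and 3 px), computed as masked
local moments over brown-voted pixels only so region boundaries do not
contaminate the texture estimate.  The split is a diagonal-Gaussian
likelihood fitted on reference tiles.  The window posterior is the
fraction of pixel votes per class.  On ten 384×384 slides spanning
TPS 4–96% this recovers the true TPS within < 2 percentage points.

## Concordance statistics

- **Lcc** uses the original population-moment estimator
  `2·cov(x,y) / (var(x) + var(y) + (mean(x) − mean(y))²)` (1/n moments);
  it equals 1 iff the scores agree elementwise and is undefined (NaN) for
  constant input.
- **Δ (inter-rater variability)** is the mean absolute difference over
  unordered rater pairs; for three raters this equals the 1/6-weighted
  sum over ordered pairs, so the two printed readings of the summation
  coincide.
- **OPA/NPA/PPA** treat the *first* score vector as the reference; empty
  strata yield NaN, and NaN is written to CSV as an empty cell, never
  silently dropped.
- **Restricted concordance** recomputes the report on slides whose Δ
  stays below each threshold and reports the included-slide fraction;
  subsets smaller than two slides are flagged undefined.
- **Leave-one-out median** compares each score source (m visual + 1
  automated) with the per-slide median of the remaining sources.
- The consolidated visual reference is the per-slide median; for an even
  number of scores the mean of the central pair is used.
- Status boundary: TPS ≥ cut-off → positive (the clinical "TC ≥ 25%"
  convention).

## Problem sizes used by the test suite and acceptance script

Desk-scale settings keep the full workflow CPU-friendly: 32×32 patches
(3-class reduced scheme {TC+, TC−, other}; "other" pools the remaining
six classes, including the macrophage confuser), network width 16,
2000 training iterations, 50 labeled patches/class + 5000 unlabeled,
held-out evaluation patches from a disjoint slide, and 10 scoring slides
of 384×384 px spanning TPS 4–96%.  The comparative experiment trains the
AC-GAN and the fully-supervised baseline on identical data across seeds
and compares mean best held-out accuracy and slide-level Lcc against the
true TPS; it keeps the labeled pool at exactly the stated 50 patches per
class (rotation augmentation, which quadruples the effective labeled
budget, is part of the standard pipeline protocol but is disabled in
this controlled comparison).  The acceptance script runs two seeds of this comparison plus
the oracle end-to-end check and a spectral-normalization check.

## Known limitations

- Synthetic realism, as above; absolute accuracy numbers do not transfer
  to clinical material.
- At desk scale the 3-class task is easy enough that both the AC-GAN and
  the supervised baseline operate near their accuracy ceiling, so the
  semi-supervised margin is small; the comparison is directional, not an
  effect-size estimate.
- Sliding-window aggregation cannot resolve class structures much smaller
  than the window; scoring accuracy assumes region scale ≳ window scale,
  as in real tumor nests at the working magnification.
- No confidence intervals are attached to the concordance coefficients.
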