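# Methods

## Scope and model

`earseg` classifies SLIC superpixels of pixel-aligned nine-channel canopy
stacks into ear and leaf, after masking soil, and evaluates the resulting
ternary masks at the pixel level. The package assumes registration across
cameras is done upstream; stacks arrive as 8-bit grids and stay 8-bit
through preprocessing. All grids use 0-based (row, col) indexing with the
origin at the top-left.

## Preprocessing

The only preprocessing is an odd-sized box (mean) blur applied to each
channel independently (default 3×3). Its purpose is purely to damp small
registration errors, for which any small low-pass suffices; the box filter
keeps the operation linear, fast and testable (blur(a)+blur(b) = blur(a+b)
within one intensity unit of rounding). Values are rounded half-up and
clamped to [0, 255]. The blur is applied immediately after loading, before
soil masking and superpixel computation.

## Cloudiness index

CT = 1 − E/(E₀·cos z) with E₀ = 1360 W/m². CT ≤ 1 always, CT = 1 exactly
at E = 0, and CT may be negative under cloud-edge irradiance enhancement —
negative values are retained, not clamped. z ≥ 90° is rejected (the
clear-sky expectation is non-positive and the index undefined). Scenes
with CT < 0.90 are treated as direct-sun; the boundary CT = 0.90 counts as
diffuse (strict inequality, an arbitrary but fixed convention). Note the
direction: clear sky ⇒ E large ⇒ CT small. CT decreases strictly in E at
fixed z, and decreases as z grows at fixed E > 0.

## Soil/plant threshold

The soil threshold is the first local minimum of the smoothed 256-bin
histogram of the 800 nm channel; pixels above it are plant. Numerical
choices, all configurable:

- **Smoothing**: moving average over 5 bins (raw histograms of small
  images have spurious minima).
- **Valley qualification**: a bin t qualifies only if h(t) ≤ both
  neighbours, a preceding mode of at least 5% of the histogram maximum
  exists, and h(t) lies below 50% of the largest bin on each side. The
  last two conditions reject noise dips in the dark tail and shallow dips
  riding on top of a single mode — without them, sampling noise in a
  bimodal histogram's left tail can masquerade as a valley.
- **Degenerate histograms** (single-class images) raise a typed error; the
  masking routine falls back to a configured constant (default 128).

Under direct sun, pixels at or below the NIR threshold (plus a
configurable margin, default 0) are re-examined in the 490 nm channel:
those *below* the blue threshold are reassigned to plant. The physical
reading: shadows are lit by blue-rich skylight, so shaded soil stays
comparatively bright in blue while shaded leaves absorb it. The blue
threshold defaults to Otsu's method over the low-NIR population and can be
pinned to a constant. The rule can only flip soil→plant, never the
reverse.

## Superpixels

SLIC runs on the RGB composite converted to CIELAB (sRGB primaries
assumed); the label grid indexes regions in every aligned channel with no
re-clustering. Full-frame parameters are 1500 target regions, compactness
10, 30 iterations. Two desk-scale adjustments:

- `SlicParams.scaled_to` scales the region target with pixel count so mean
  region size is preserved for real imagery. For the synthetic scenes the
  package instead uses a fixed target of 300 regions at 512×512 (≈870 px
  per region), keeping regions clearly smaller than the generated organs —
  the sizing principle the field protocol follows. Under that setting the
  worst per-ear best-region purity observed across seeds is ≈0.92.
- `min_size_factor` is lowered from skimage's default 0.5 to 0.25: on busy
  canopy textures the default post-merge collapses the region count far
  below the target.

Superpixels are computed on the full frame and intersected with the soil
mask afterwards; a superpixel is eligible for classification when the
majority of its pixels are plant (threshold configurable).

## Features

29 per-superpixel features: means of the six narrow bands; normalized rgb
chromaticity and HSV of the mean RGB color (R=G=B=0 maps to r=g=b=1/3 and
hue 0); fifteen vegetation indices; DAS and CT. Indices are computed from
superpixel-mean band values (means-first), on a [0, 1] scale so indices
with additive constants (OSAVI, EVI2) behave as with reflectances; no
radiometric calibration is performed. Zero denominators yield 0 with a
logged flag. The index registry is data, not code: the ten named indices
use their standard literature formulas, and the remaining five slots
(GRVI, EVI2, MCARI, ExG, GLI) are explicitly replaceable.

## Labelling and datasets

Brush-region label images convert to superpixel labels by: discard if
labelled pixels of both classes are present (mixed) or fewer than two
labelled pixels exist; otherwise assign a class whose labelled pixels
reach ≥10% of the superpixel's total pixel count; below that, ignore.
"Fewer than two pixels" is read as fewer than two *labelled* pixels, and
the 10% is taken against the superpixel's total area — both documented
interpretations. Labelled rows are shuffled and split 80/20 per seed.

Evaluation annotations use a deterministic pixel grid: rows and columns at
the centers of equal subdivisions inside a 5% margin; the default 18
points form 3 rows of 6. The annotation tool shows a zoomed crop per pixel
and takes a three-way decision (background / ear / uncertain), appending
records to CSV as they are made so an aborted session is resumable.

## Classification

Features are standardized with training-set means and *population*
standard deviations (either convention is defensible; population is fixed
for test stability); zero-variance features are dropped with a warning and
other tables reuse the training parameters. The production classifier is
the tuned SVM (RBF, C=100, γ=0.1). Grids for retuning span those optima
(SVM C ∈ {0.1…1000}, γ ∈ {0.001…1}, kernel ∈ {rbf, linear}; MLP hidden ∈
{10, 50, 100}, activation ∈ {relu, tanh}, α ∈ {1e-4…1e-2}; RF trees ∈
{100…500}, depth ∈ {None, 10, 20}, leaf ∈ {1, 5}, split ∈ {2, 10}). Folds
are stratified and seeded; grid-search ties break toward the simpler model
(smaller C, fewer hidden units, fewer trees), making the result invariant
to grid ordering.

Sequential backward feature selection evaluates all (n−1)-subsets per step
with the same folds, removes the feature absent from the best subset (ties
break by column order), and records the accuracy trace. The named feature
presets from the selection study (13 for SVM, 15 for MLP, 8 for RF) ship
as selectable configurations; where the preset names "G, B" the package
uses the normalized chromaticity columns, as those are the features in the
29-set. A learning-curve utility (train vs CV accuracy per training size)
supports the overfitting audit.

## Evaluation

Pixel metrics merge soil and leaf into "background" to match the
three-button protocol; uncertain annotations are discarded before any
metric. Precision, recall and F1 take ear as the positive class. Per-group
metrics (date, nitrogen, trial) pool confusion counts across images before
computing the F1 family; a group whose pooled counts leave precision or
recall undefined reports NaN rather than failing. Cohen's κ uses each
annotator's own marginals (the standard definition); pairs with an
uncertain label on either side are dropped, and the degenerate case of two
identical constant annotators defines κ = 1.

## Synthetic canopy generator

The generator emulates the statistical structure the pipeline exploits,
not photorealism:

- **Geometry.** Soil background; overlapping elongated leaf ellipses
  (semi-axes ≈25–60 × 5–12 px at 512 scale) to a target cover of 0.45;
  ear ellipses with awns (semi-axes ≈44–58 × 20–27 px), placed wholly in
  frame, rejecting placements that would bury an earlier ear. Ears are
  added until a target ear fraction (±0.02 self-audit) or an exact count
  is reached.
- **Spectra.** Each class has per-channel (mean, sd) signatures: soil dark
  at 800 nm and bright in blue; leaves green-dominant with a strong NIR
  plateau; ears brighter and yellow-shifted. `stage_similarity` ∈ [0, 1]
  linearly pulls the ear signature toward the leaf signature (1 = heading,
  identical colors).
- **Organ-level variation.** Every organ instance receives its own
  per-channel mean offset (sd 15 by default), emulating pose and lighting
  differences. This is essential: superpixel means average away pixel
  noise, so without organ-level spread the classes would remain separable
  even with identical signatures, and the heading-stage degradation could
  not manifest. A side effect is that organ-overlap statistics (ears carry
  one full offset, leaf regions average several overlapping leaves) remain
  a weak class cue even at similarity 1; the package's
  indistinguishability control therefore switches organ variation off and
  samples equal-geometry regions, isolating the color signal.
- **Illumination.** Diffuse mode renders signatures directly. Direct mode
  casts a binary smooth-noise shadow field over vegetation (35% cover,
  factor 0.15) with wavelength-dependent skylight retention (blue keeps
  ≈45% of its light in shadow, NIR ≈5%), and sweeps soil through a smooth
  sun-fleck/penumbra gain continuum up to 1.3. This merges shaded leaves
  into the soil NIR mode — the confusion the blue-channel refinement
  exists for — while keeping the soil side of the histogram unimodal.
- **Experiments.** `generate_experiment` renders a dates × plots grid in
  which ear cover grows over the season and with nitrogen input, stage
  similarity decays from a configurable start (default 0.8) to 0, plots
  alternate diffuse/direct illumination, and DAS/irradiance metadata are
  written to a CSV sidecar.

What passing tests on these scenes do **not** show: robustness to real
registration artifacts, specular glint, soil moisture variation, canopy
depth effects, or organ textures — the generator has none of these.

## Problem sizes

The test suite and the reproduction script run a desk-scale study: 512×512
scenes, 6 dates × 4 plots for training (~2400 labelled superpixels), four
held-out scenes per stage condition with 120 grid pixels each, and
300-region SLIC. These sizes were chosen so the full study completes in a
few minutes on one CPU while keeping every effect (accuracy regime,
heading-stage F1 dip, nitrogen ordering, soil-mask gain) comfortably away
from its decision boundary.

## Known limitations

- The five filler vegetation indices are stand-ins; swap the registry if a
  specific supplementary index set is required.
- The interactive annotator is terminal-based; the brush-labelling web
  workflow is out of scope (label images are read from files).
- B-spline multi-camera registration, stereo depth, spectrometer
  calibration and CNN baselines are out of scope.
- The generator's blue-sky shadow model is a two-parameter caricature; it
  provides the *sign* of the effect the blue rescue uses, not calibrated
  radiometry.
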