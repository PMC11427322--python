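# Methods

This note documents the estimators, the psychometric scoring, the modeling
chain and the synthetic-data design: what each computes, the conventions
chosen where several were defensible, and what the test suite does and does
not establish about real photographs.

## Image preprocessing

Input photographs are center-cropped to 4096 × 2048 and downsampled to
640 × 320 with box (area-averaging) resampling; images already at the
working size pass through untouched. Box resampling was chosen because the
downscale factor is large (≈ 6×) and aliasing from point sampling would
corrupt the fractal and spectral estimates. All indicators are computed at
the 640 × 320 working size; the extraction config can disable the crop for
images that arrive pre-cropped.

## Greenery

A pixel counts as vegetation-colored when its HSV coordinates fall
inclusively within hue 50–170°, saturation 20–100 %, value 10–100 %
(degrees/percent convention; an 8-bit OpenCV-style reading of the same
numbers is available via config, but on that scale hue 50–170 spans
cyan→magenta, which is not a plausible plant band — hence the default).
The greenery percentage is the green-pixel share × 100, and the modeling
uses its square root, consistent with square-root-law compression of
perceived texture density. Inclusive threshold comparisons carry a 1e-9
guard band: HSV values of 8-bit pixels are rationals spaced ≥ ~1e-5 apart,
so the guard absorbs float rounding only and makes the boundary semantics
exact (verified against a per-pixel rational-arithmetic oracle).

The counter does not distinguish live plants from green furniture or
pictures of plants; it is a color criterion, nothing more.

## Box-counting conventions

All box grids are anchored at the top-left corner; partial boxes at the
right/bottom edges are counted; no multi-offset averaging. The box-size
ladder is powers of two from 2 up to min(H, W)/4; "small" is the lower half
of the ladder, "large" the upper half, "overall" all of it (halves overlap
on ladders shorter than six rungs so each window keeps the three points a
log–log regression needs). Dimensions are ordinary least-squares slopes of
log N versus log(1/ε).

* **Shape fractal** — box dimension of a brightness edge map: Gaussian
  smoothing (σ = 1), Sobel gradient magnitude, hysteresis thresholds set
  from the positive-gradient distribution (high = 90th percentile,
  low = high/2), then skeleton thinning so the box count measures the curve
  rather than the stroke width. A uniform image has no edges and reports 0
  with a degenerate-input flag.
* **Geometric fractal** — box dimension of the above-median set of a
  channel field; the median split keeps the occupied set near half the
  pixels for any monotone intensity transform. Constant fields report the
  plane-filling value 2.0, flagged.
* **Statistical fractal (DBC)** — differential box counting on the
  intensity surface: for box size ε each ε × ε cell contributes
  ⌈(max − min)/h⌉ + 1 with intensity box height h = ε·range/min(H, W), so
  the unit intensity range spans as many boxes as the shorter spatial side.
  Contract range [2, 3].
* **Color fractal** — box counting in the joint (x, y, R, G, B) space with
  spatial and color box edges shrinking at the same relative rate. Its
  ladder uses coarse relative sizes (1/8, 1/4, 1/2 of the short side)
  because the 5-D box population grows as (S/ε)⁵: finer boxes outnumber the
  pixels and the count saturates at the sample size instead of tracking the
  color-space geometry. Contract range [2, 5]; constant-color images sit at
  2, and images with abrupt, varied color transitions score higher than
  smooth gradients.

### Known bias of the DBC estimator

On spectrally synthesized fractional-Brownian surfaces the DBC estimate of
the analytic dimension 3 − H is biased low, strongly so for rough surfaces:
at 512² the error is ≈ −0.05 at H = 0.8 but ≈ −0.18 at H = 0.5 and ≈ −0.30
at H = 0.2 (averaged over seeds, large-scale window 16–128). Three causes,
verified numerically: (i) the sup of a sampled Gaussian self-affine field
over an ℓ-window grows like σ(ℓ)·c(ℓ) with c(ℓ) increasing ≈ √log ℓ², which
flattens the count slope; (ii) the ⌈·⌉ + 1 floor adds ≈ 1.5 boxes per cell
and compresses the slope further; (iii) pixel sampling removes sub-Nyquist
roughness. Larger fields, oversampled synthesis and absolute-partition
counting each improve the estimate by ≤ 0.05, so the bias is a property of
the estimator class, consistent with the saturation reported for DBC-type
estimators in the texture literature. Consequences: DBC values are treated
as a relative roughness index (their ordering in H is strictly monotone and
tested), and the corresponding analytic-recovery checks in the acceptance
suite pass at H = 0.8 but fail at H = 0.2 and H = 0.5 at the ±0.1 tolerance
asserted there — the assertions are left at that tolerance deliberately
rather than widened to fit the estimator.

## 1/f fluctuation

The mean-removed field is Fourier-transformed; power is radially averaged
over 16 log-spaced frequency bins between the second radial bin
(2/min(H, W) cycles/pixel) and half the Nyquist frequency, excluding DC
leakage and the aliased top octave. The reported index is the
amplitude-spectrum exponent (half the negative power-spectrum slope), so
pink 1/f structure maps to 1 and white noise to 0. Recovery of planted
exponents in [0.5, 2] is accurate to well within ±0.1 at 512².

Hue enters the texture estimators as a linear field on [0, 1] — a known
approximation that misbehaves only for scenes whose hues straddle the
0°/360° wrap, which the synthetic scenes avoid by construction.

## IRCS scoring

Eleven items — 4 Being Away, 4 Fascination, 3 Extent — rated 1–5.
Reverse-keyed items (Extent only) are inverted as 6 − x before averaging;
which Extent items are reversed is configurable, with EX2/EX3 as the
packaged default since the item text is not published. Subscale scores are
item means; the overall score is the mean of the three subscale means; the
restorative-experience score is the mean of its five items. Incomplete
response blocks are rejected, not imputed, mirroring the exclusion-based
handling of incomplete participants in crowd-sourced administration.
Photo-level summaries use the sample (n−1) standard deviation, 0 for a
single rater.

## Modeling chain

Predictors are standardized to z-scores (sample SD) over the full photo
set; the stored means/SDs travel with every saved model so it can be
applied to raw features later. VIF pruning recomputes all VIFs after each
removal and drops the highest non-protected VIF until all retained
indicators sit below 5; √greenery is protected (never removed, still a
regressor); ties break by column order so runs are deterministic. The
train/test split draws 10 of 60 photos uniformly at a caller-supplied seed
— there is no hidden default seed. Cross-validation assigns folds by a
seeded shuffle followed by contiguous blocks; RMSE is computed per fold and
averaged, with the SE taken as SD/√k across folds (the per-fold-then-average
convention, chosen where pooling would also have been defensible). The
lasso objective is (1/2n)·RSS + λ‖β‖₁ with an unpenalized intercept — stated
explicitly because λ is only meaningful relative to the scaling; λ grids are
100 log-spaced values from the data-derived λ_max (smallest λ with all
coefficients zero) down to 10⁻⁴λ_max. λ = 0 falls back to ordinary least
squares. The published coefficient tables are consumed as coefficients on
the standardized scale and never refit, so the objective scaling cannot
affect their predictions.

`RestorativenessLasso.fit(seed)` composes the chain and returns a results
object carrying the selected model, the CV curve, the VIF trace, the split
and train/test RMSE, with `summary()`, `predict()` and `plot_cv_curve()`.

## Synthetic data

The generators define the study-shaped conditions used throughout the
tests.

**Scenes** (640 × 320 by default, 60 per study set, greenery targets
spanning 0–60 %): a non-green background (flat, sat/val gradient, or
1/f-textured brightness with per-scene amplitude), large uniform wall
panels recoloring hue/saturation in a per-scene palette of 2–10 non-green
hues, furniture and clutter rectangles that likewise recolor hue/saturation
while preserving the brightness field, "busy" shelf regions whose per-pixel
hue variety is set by an independent chroma-variety knob, and small
independent hue/saturation micro-jitters. Plant blobs are ellipses in a
near-uniform scene-level green placed strictly inside the detection band;
exactly ⌊target % · area⌋ pixels are painted green, so the measured
greenery hits the target to pixel rounding and a target of 0 yields no
green pixel (generator and measurer cross-validate on every render).

The design separates three axes that are entangled in naive renderings and
separated in real offices: greenery, luminance texture, and chromatic
variety. Foliage is rendered with low color variety (plants smooth the
color field rather than cluttering it), and color complexity is driven by
roughness-free sources (panels, hue-only recolorings), keeping
corr(√greenery, color fractal) near zero and the color fractal's VIF
comfortably below the pruning threshold — matching the published situation
in which the color fractal survives pruning and carries an independent
effect. What the scenes do **not** emulate: perspective, lighting
direction, shadows, recognizable objects, depth — so passing tests show the
statistical chain recovers planted structure under study-shaped conditions,
not that the indicators capture human scene perception.

**Ratings**: photos are dealt into 12 greenery-balanced groups of 5 by
sorting on greenery and serpentine (boustrophedon) dealing, which keeps
group means within a fraction of a rating point of the grand mean. Each
group has its own raters (100 by default); the latent photo mean is
a + b·√g + c·colorfractal with defaults a = 2.8, b = +0.12, c = −0.10;
each of the 11 item responses is round-then-clamp(latent + participant
offset + ε) with ε ~ N(0, σ = 0.6) and participant offsets ~ N(0, σ/2),
the minimal two-level response model (the study reports no richer noise
structure). The offset default induces within-photo rating SDs below 1,
qualitatively matching the reported consensus across raters. Reverse-keyed
items are stored inverted so scoring recovers the latent scale.

**Analytic fixtures**: Sierpinski carpet masks (dimension log 8/log 3 —
recovered exactly on the power-of-three ladder and within ±0.05 on the
dyadic default), spectral-synthesis fBm surfaces (amplitude ∝ f^−(H+1)),
and planted-exponent spectral noise.

## Degenerate inputs and numerical choices

Empty edge maps, constant fields and flat spectra map to documented
fallback values with warning flags (collected, not raised, during batch
extraction); all-empty masks and constant fields where no estimate is
meaningful raise typed errors. Lasso convergence uses a 1e-10 duality-gap
tolerance and up to 2·10⁵ iterations; KKT conditions of the fitted optima
are verified to 1e-6 in the tests. Box-count and spectral slopes agree with
naive-loop reference implementations to 1e-9 on 32² instances.

## Problem sizes

The validation suite uses 512² fields for fractal/spectral recovery, 60
scenes at 640 × 320 for the study-shaped experiments, and 50 rating
replicates (planted and null) for the recovery rates; these sizes give
stable estimates while keeping a full run of the suite and the acceptance
script in the minutes range on a single CPU.

## Known limitations

* The 19-indicator catalogue reproduces the published count and contains
  all post-pruning variables of the published correlation table, but the
  source's own indicator definitions are in an unavailable supplement; the
  estimator formulas here are standard literature choices.
* DBC's negative bias on rough surfaces (above).
* Whether fractal indices should be computed on the display-size images or
  the full-resolution crops is unstated in the source; both are available
  via config, with the display size as default.
* The identity of the reverse-keyed Extent items is a configurable guess.
* Scene realism is statistical, not perceptual; no human has rated the
  synthetic scenes.
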