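# Methods

This note documents the models, numerical choices and design decisions
behind `stripsense`, and what its synthetic-scene tests do and do not
establish about real photographs.

## The measurement model

A DPD-impregnated pad oxidizes in the presence of free chlorine to a magenta
product; more chlorine means a darker, more saturated pad, hence a smaller
RGB sum in a photo. The package models the mapping in two stages:

* **color recovery** — undo the capture conditions (camera cast, lighting,
  resolution, perspective) so that the pad's mean (R, G, B) is comparable
  across phones and scenes;
* **calibration** — an OLS regression of concentration on pad color.

Calibration families (all fit with statsmodels OLS; rank-deficient designs
raise a typed error rather than pseudo-inverting):

| family | design | role |
|---|---|---|
| `linear_sum` | 1, R+G+B | proof of concept; the channel sum falls with concentration |
| `multiple_rg` | 1, R, G | per-channel weights; per-term p-values reported so a blue-channel exclusion can be justified on any dataset |
| `polynomial_sq` | 1, R, G, B, R², G², B² | the selected model; captures the curvature that shows up as U-shaped residuals in the linear fits |

Backward stepwise selection greedily removes the single term whose removal
lowers the Gaussian-likelihood AIC the most and stops when no removal
lowers it; the intercept is never removed. Exact AIC ties — which arise
only for noiseless exact fits, where the AIC degenerates — break toward the
smaller model. Note a structural property of AIC selection: a truly inert
predictor is *retained* with asymptotic probability P(χ²₁ > 2) ≈ 0.16
regardless of sample size, so stepwise runs on data with no blue effect
shed both blue terms on only ~80% of random datasets. This is inherent to
the criterion, not a defect of the implementation.

Predictions evaluate the raw linear predictor and may be negative. Negative
values are meaningful — a blank pad's color can sit "above" the zero-chlorine
calibration point — and the classification stage, not the regression, maps
them into the lowest tier. Squared terms extrapolate poorly outside the
trained color range, so calibration data should span the full range
including zero-chlorine strips.

A published coefficient set ("paper-2022") ships as a built-in model for all
three families. It was fit to the original field deployment's photographs;
it is provided for reproducibility of that deployment's arithmetic and is
not expected to transfer to synthetic scenes or other cameras. The
polynomial family's predictor-to-channel binding (x₁→R, x₂→G, x₃→B) is an
assumption recorded in the model metadata: the published fit never states
it, and it cannot be verified from the printed results.

## White balancing

Two diagonal (per-channel gain) transforms, computed in floating point and
clipped to [0, 255], with quantization only at file boundaries:

1. **Gray world**, whole photo: gains ((R̄+Ḡ+B̄)/3)/channel-mean, which
   equalizes the channel means. The published description of the second
   balance admits two mutually reciprocal readings; the default here is the
   standard white-patch gain (below), with the literal reciprocal available
   behind `balance.white_variant: reciprocal`.
2. **White reference**, strip crop: gains 255/white-mean, where the white
   mean is taken over pixels whose *minimum* channel exceeds a threshold
   (default 200) — near-neutral bright pixels, i.e. the white strip body
   and not the colored pads. The white pixels are selected from the strip
   crop rather than any printed background patch.

Because both balances and the lighting casts are diagonal transforms, the
white-reference step cancels a cast exactly up to noise: for scene pairs
differing only in cast, recovered pad colors agree within a couple of
units per channel (the test tolerance is ±5).

## Geometric chain

Processing order: gray-world balance → fiducial detection → alignment →
rectangle detection → strip crop → white-reference balance → pad regions →
inscribed-circle extraction. Every stage returns a typed failure value
(`fiducial` / `rectangle` / `strip` / `pad`) instead of raising, so batch
reports can tally failures by stage.

* **Fiducial**: the QR-lookalike is three nested-square finder patterns
  (dark 7×7-module ring, white 5×5, dark 3×3 core) at three corners of a
  white block. Detection uses Gaussian blur, a Canny edge gate, and
  marching-squares contours at an Otsu level; a finder pattern is three
  concentric closed contours with nested-square area ratios. No QR payload
  exists or is decoded. Corner localization re-extracts each contour at the
  *local ink/paper midpoint* level (an off-midpoint threshold shifts the
  subpixel crossing off the physical edge and biases the fit's scale) and
  fits square sides by total least squares, intersecting adjacent sides.
  All 36 corners (3 patterns × 3 contours × 4 corners) feed one projective
  estimate; using the inner contours too is what keeps the extrapolated
  frame accurate far from the block (worst-case over the 50-scene battery:
  fiducial 0.7 px, rectangle 2.3 px).
* **Alignment** warps the photo so the fiducial block lands at its nominal
  position in a fixed 1024×768 canonical frame; all later thresholds (e.g.
  minimum rectangle area) are therefore scale-free.
* **Rectangle**: hole-filled connected dark components (Otsu), gated by
  area, tall aspect ratio and darkness; the largest survivor wins, with
  corners from a subpixel contour of its outline.
* **Strip**: the largest bright component inside the rectangle, aspect-gated
  to be strip-shaped; lateral placement within the 3×-width rectangle is
  free by design.
* **Pads**: placed geometrically at fractions of the strip length (total
  pad 0.10 from the top, free pad 0.45; the fiducial defines "up", and a
  flipped orientation swaps them). The sampled pad polygon is a square of
  0.64× the strip width — deliberately inset from the ~0.76× physical pad
  so that the inscribed circle samples the pad interior; sampling out to
  the pad edge picks up resampling spill from the white surround (errors
  of several units per channel at mid resolution, versus <1 inset).
* **Extraction**: mean RGB over pixels whose centers lie strictly inside
  the inscribed circle (boundary ties excluded — reproducible integer
  geometry); a minimum pixel count guards against degenerate circles.

## Synthetic scenes

The renderer draws the standard background in a 1024×768 design frame:
mid-gray card (so the gray-world assumption is neither trivially true nor
pathologically violated), black rectangle 200×580 px, white strip 66×500 px,
fiducial block 160 px with 56 px finder patterns, pad squares of 50 px.
"Paper white" is 215, not 255, so multiplicative casts never clip.

* **Concentration → color**: piecewise-linear interpolation of per-channel
  anchors at 0, 0.1, 0.2, 0.35, 0.5, 1, 2, 4 mg/L. Anchors put each tier's
  mean at the midpoint of the observed per-tier channel ranges (red 122–193,
  133–182, 98–170; green 125–193, 111–170, 57–146; blue 135–179, 128–175,
  114–170 for the tiers ≤0.2, 0.2–0.5, >0.5 mg/L) and make the channel sum
  strictly decreasing on [0, 4]. Per-strip Gaussian color noise (sd 6,
  default) is truncated to the tier's bounds, so a drawn color always
  classifies into the tier it was generated for. Above 4 mg/L (the
  regulatory MRDL) the color saturates at the 4 mg/L anchor.
* **Lighting casts**: diagonal gains — warm (R×1.15, B×0.87), cool the
  reverse. Magnitudes keep paper white ≤ 250 pre-balance.
* **Tilt**: a pinhole model rotating the card plane about its horizontal
  axis (focal length 2× the long edge), applied as a projective warp;
  ground-truth geometry transforms with the same map. Tilt is validated to
  ±10°.
* **Resolution**: long-edge budgets high 1024 (native), mid 640, low 320,
  by area resampling; the low level additionally pixelates (0.5× down,
  nearest-neighbor up), emulating a legacy 2 MP-class camera. Under these
  conditions low-resolution scenes essentially always fail at the fiducial
  stage — the finder-ring structure is destroyed — which reproduces, in
  exaggerated form, the field observation that processing failures
  concentrate in the lowest-resolution phone. The transition is sharp
  (a long edge of ~450 px processes reliably).
* **Ground truth** records geometry in final pixel coordinates and in the
  canonical design frame, the pad colors before lighting/noise, and the
  same colors in *reference-white coordinates* (×255/215): after the
  white-reference balance the pipeline works in a frame where the strip
  body is (255, 255, 255), so recovered pad colors are compared against
  the reference-white truth.

What the synthetic scenes do **not** emulate: vignetting and shadow
gradients, specular glare, chromatic aberration, JPEG artifacts, non-planar
strips, reagent kinetics (the 2-minute read window is metadata only), and
pad textures. Passing tests therefore demonstrate the correctness and
internal consistency of the chain under controlled capture variation, not
field performance on real photographs.

## Evaluation machinery

Confusion matrices are stored rows = predicted, columns = true. Tier
boundaries are half-open on the left ((lo, hi]); 0.2 belongs to the lowest
multiclass tier and 0.5 to the middle one (and to the binary positive
class ≤0.5). Per-class precision/recall with a zero denominator are
reported as 0, flagged, and included in aggregates — a documented,
configurable convention. Reported percentages round half-up to whole
percents. Stratified splitting uses largest-remainder apportionment of the
training fraction across concentration groups (67% of the published
six-group campaign reproduces the 129/63 split exactly), uniform within
groups given the seed. For proportion comparisons across more than two
groups, a single pooled two-proportion z statistic is not defined, so all
pairwise z tests plus an overall 2×K chi-square are reported instead.

The conditional-probability module needs a model the published description
leaves open: the priors and the dependence between repeated samples. It
fixes one explicit choice — all samples at a location share one unknown
true tier, the prior over tiers is the empirical true-class marginal of the
supplied confusion matrix, and classifications are conditionally
independent given the true tier. Posterior case probabilities are then
exact total-probability sums. Published case bounds for the original
deployment are not asserted anywhere: the deployment's own printed
likelihood (10/74) cannot be reconciled with its printed combined matrix
under either row/column orientation, so both orientations are supported
behind a flag and the discrepancy is simply documented.

## Problem sizes and determinism

The shipped batteries use 120 scenes (end-to-end train/test), 50 scenes
(localization) and 16 per resolution level (failure rates) — sizes at which
the checked properties are stable across seeds while a full run stays in
the minutes range on one core. All randomness flows from
`numpy.random.default_rng` seeded from a single user seed; a fixed seed
yields bit-identical scenes, manifests and reports.

## Known limitations

* Pad localization is geometric (fractions of the strip length), not
  content-based; a strip type with different pad placement needs the two
  fraction parameters changed.
* The fiducial detector assumes near-upright capture (≲10° of roll); it
  orders finder-pattern corners by axis-aligned extremes.
* One strip per photo; no glare/shadow diagnostics.
* The calibration is only as good as its training colors; models trained on
  synthetic scenes say nothing about real strips, and the published
  built-in model says nothing about synthetic scenes.
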