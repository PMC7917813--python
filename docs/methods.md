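# Methods

## Problem and model

The package decides, per video frame, whether a driver's eyes are open or
closed; a closed-eye frame is labeled drowsy.  The decision is
"instantaneous": no temporal model is used by default (an optional
majority-vote smoothing window exists in the CLI but is off).  The signal
exploited is texture: an open eye-pair band contains strong, multi-oriented
gradients (sclera/iris/pupil boundaries), while a closed eye is smooth
eyelid skin with at most a faint crease.

### Preprocessing

Frames are blurred with a normalized Gaussian (3 x 3, sigma 0.5, reflect
borders — constants are fixed points and total intensity is conserved), then
light-compensated by contrast-limited adaptive histogram equalization
applied to each color channel independently.  The CLAHE implementation uses
per-tile 256-bin histograms clipped at `clip_limit` multiples of the uniform
bin height (default 2.0, floor of one count per bin), uniform redistribution
of the clipped excess, midpoint-cumulative lookup tables
`lut(v) = (cdf(v) - hist(v)/2) / N * 255`, and bilinear interpolation
between the four surrounding tile mappings.  The midpoint convention is what
makes a constant channel map onto itself (within one gray level for
reasonably sized tiles); a plain-CDF mapping would shift constants toward
white.  Defaults: 8 x 8 tile grid, clip 2.0, downscaling off (factor 1.0).

### ROI

Face detection is a backend contract (`detect(gray) -> [(box, confidence)]`).
Shipped backends: a ground-truth annotation replay (CSV `frame,x,y,w,h`,
0-based half-open boxes) and a bright-region heuristic sufficient for the
synthetic frames.  The eye-pair band is a fixed anthropometric sub-box of
the face box — horizontally the middle 15%..85%, vertically 25%..55% — and
is resampled to a canonical 64 x 32 patch (area averaging when shrinking,
bilinear when growing; both implemented as explicit separable weight
matrices so block means are exact).  The canonical width:height of 2:1
matches an eye-pair band, and both dimensions are multiples of the 8 px
cell so the cell grid tiles exactly.  When several faces are detected the
highest confidence wins, ties going to the largest box (the driver sits
closest to the camera).

### Descriptor

Gradients use the centered mask `[-1, 0, 1]` by default (first-order
Gaussian derivatives at sigma 1.0 are available); orientation is unsigned,
folded into [0, pi), and defined as 0 where the magnitude is 0 (the vote
mass is zero there anyway).  Votes are anti-aliased by circular bilinear
interpolation between the two nearest bin centers (bins of width pi/m,
centers at (k+0.5)pi/m, wrap modulo m).  This is the sign-safe equivalent of
the per-pixel offset formulation `alpha = b + 0.5 - gamma/(pi/m)`, whose raw
value goes negative in the right half of each bin; the tests assert the
equivalence.  The vote quantity is the gradient magnitude — weighting
orientations themselves would make the histogram dimensionally meaningless —
split `(1-alpha)rho / alpha*rho` between the two bins.

BOSH bits compare cell histograms pairwise under all cyclic shifts (see
README for the formula).  Design choices that fix the format:

* pairs are the 6 unordered cell pairs within each overlapping 2 x 2 block,
  compared first-to-second in canonical raster order (TL-TR, TL-BL, TL-BR,
  TR-BL, TR-BR, BL-BR) — comparison is asymmetric, so the order is part of
  the format; a `grid-adjacent` pair scope (all horizontally/vertically
  adjacent cell pairs across the grid) is available via config;
* bit order is block-major, then pair, then shift-major, then bin, and is
  recorded in every serialized container;
* no block normalization precedes binarization: the comparisons are
  invariant to any common positive scaling, so normalization would be a
  no-op by construction.

A 64 x 32 patch gives (8-1)(4-1) = 21 blocks x 6 pairs x 64 bits = 8064
bits.  The baseline HOG path concatenates the four cell histograms of each
block (32 values) and L2-normalizes with guard 1e-6 (672 values).

### Classifier

Bernoulli Naive Bayes for the bits, Gaussian for the baseline.  Smoothing
weight `m_weight` defaults to 2.0 with t = 2 possible feature values, which
makes the m-estimate equivalent to add-one smoothing and keeps every
conditional probability strictly inside (0, 1).  Gaussian variances use the
population convention (divide by n) with a 1e-9 floor.  All scoring is in
log space — at 8064 features the literal product of probabilities
underflows double precision by hundreds of orders of magnitude.  Ties break
to the lowest class index (classes are kept in sorted label order).
Posteriors are normalized by log-sum-exp.  A fitted two-class model over N
binary features stores exactly 2N conditional parameters plus one free
prior.

## Synthetic data generator

The generator emulates the statistical structure the descriptor measures,
not photorealism: two almond-shaped eyes (bright sclera, dark iris and
pupil discs) on a skin-toned gradient background, clipped by an eyelid whose
opening fraction ("aperture") is the class variable — closed samples draw
aperture from [0, 0.15], open from [0.5, 1.0] at full separability, the gap
narrowing linearly as `separability` decreases (by 0.25 per unit on each
side).  A pixel row of the eye is visible only when fully inside the
opening, so aperture 0 exposes nothing.  Scenario transforms: night
variants multiply intensity by 0.35 (emulating low-gain IR exposure);
glasses blend a dark band (opacity 0.35) over the upper eye margin;
sunglasses blend opacity 0.65 over the whole eye band.  Additive Gaussian
sensor noise (default sigma 0.02 in [0,1] units) is applied last and the
result clipped.

Determinism: every sample is a pure function of its parameters; dataset
sample i renders with seed `master_seed XOR i`.  Scenario assignment draws
from the requested mixture (uniform over the five scenarios by default).

What passing tests on this generator do **not** show: robustness to head
pose, motion blur, eyelash/makeup variation, specular reflections on
glasses, or real IR sensor characteristics.  Since occlusion transforms are
affine in intensity, they are invisible to the descriptor except through
their interaction with sensor noise — which is also how the generator's
difficulty ordering (bare face easiest, sunglasses/night hardest) emerges.

## Problem sizes and numerical choices

* The end-to-end evaluation uses 250 training and 100 test patches per
  class — enough for stable accuracy estimates on a single CPU in seconds.
* Conservation tolerances: cell-histogram mass equals total gradient
  magnitude to 1e-9 relative (it is exact up to float summation order).
* CLAHE clip floor: one count per bin, so tiny tiles cannot clip to zero.
* Degenerate evaluation cells (no predicted positives) report 0 with a
  logged warning rather than NaN.
* Model files store parameters via `repr` round-trip, so reloaded models
  predict bit-identically; descriptor bits pack 8 per byte MSB-first with a
  JSON header carrying the layout.

## Known limitations

* The ROI heuristics assume a roughly frontal, centered face; no tracking.
* The bright-region face backend is only meant for controlled/synthetic
  imagery; real deployments should plug in a trained detector through the
  backend contract.
* Only per-frame decisions are modeled; blink-duration or PERCLOS-style
  temporal statistics are out of scope.
* The Bernoulli model treats bits as conditionally independent given the
  class; BOSH bits within a pair are strongly dependent, so posteriors are
  overconfident even when the decisions are good.
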