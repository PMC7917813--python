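# drowsyhog

Instantaneous driver-drowsiness detection from single video frames.  The
package classifies the driver's eye state (open vs. closed; a closed-eye
frame counts as drowsy) using a compact binary texture descriptor — a
**b**inarized **o**rientation-**s**hifted **H**OG, "BOSH" — and a Naive
Bayes classifier written from first principles.  It is aimed at people
building or studying camera-based driver-monitoring pipelines who want a
fully inspectable, dependency-light alternative to deep models, and at
anyone who needs a well-tested reference implementation of shifted-histogram
binary descriptors.

## Method

For an eye-pair patch (canonically 64 x 32 px) the pipeline computes per
pixel the gradient magnitude and unsigned orientation

    rho = sqrt(Lx^2 + Ly^2),   gamma = atan2(Ly, Lx) mod pi,

with `Lx`, `Ly` from the centered mask `[-1, 0, 1]` (or first-order Gaussian
derivatives).  Each pixel votes its magnitude into an 8-bin orientation
histogram over its 8 x 8 cell, anti-aliased by splitting the vote between
the two nearest bin centers.  Within every overlapping 2 x 2-cell block,
each of the 6 cell pairs (c1, c2) is compared under all cyclic bin shifts
eps = 0..7:

    b_{c1 c2}(k, eps) = 1  iff  v_{c1}(k) >= v_{c2}((k + eps) mod 8),

giving 64 bits per pair and 8064 bits for a 64 x 32 patch.  Because only
order relations between gradient magnitudes enter, the descriptor is exactly
invariant to affine illumination changes `a*I + c` (a > 0) — verified
bit-for-bit in the tests.

The bits feed a Bernoulli Naive Bayes classifier with m-estimate smoothing,

    P(x_i = 1 | w_j) = (n_c + m * alpha) / (n + m),   alpha = 1/t, t = 2,

class priors estimated as frequencies, and MAP decisions computed in log
space.  A real-valued block-normalized HOG descriptor with a Gaussian Naive
Bayes model is included as the comparison baseline.  Frame preprocessing
(Gaussian blur sigma 0.5 over 3 x 3, per-channel contrast-limited adaptive
histogram equalization, optional downscaling), face/eye-pair ROI extraction
with pluggable detector backends, a five-scenario synthetic eye-patch
generator (bare face, glasses, sunglasses and the two night variants) and a
per-scenario evaluation report complete the pipeline.

## Worked example

Generate synthetic data, train both feature paths, and evaluate on a held-out
set (moderate sensor noise 0.12 on both sides):

```
drowsyhog simulate --out demo/data --n 100 --seed 7 --noise-sd 0.12
drowsyhog train --manifest demo/data/manifest.csv --features bosh --out demo/bosh.model
drowsyhog train --manifest demo/data/manifest.csv --features hog  --out demo/hog.model
drowsyhog simulate --out demo/test --n 40 --seed 1007 --noise-sd 0.12
drowsyhog evaluate --model demo/bosh.model --baseline-model demo/hog.model \
    --manifest demo/test/manifest.csv --out-prefix demo/report
```

which prints:

```
Scenario        Drowsiness F1-Score (%)  Non-Drowsiness F1-Score (%)  hog AC (%)  advhog AC (%)
Bareface        100.00                   100.00                       100.00      100.00
Glasses         100.00                   100.00                       100.00      100.00
Sunglasses      93.33                    88.89                        83.33       91.67
Night-BareFace  83.33                    85.71                        76.92       84.62
Night-Glasses   85.71                    85.71                        80.95       85.71
Average         92.48                    92.06                        88.24       92.40
```

Rows are recording scenarios; the F1 columns score drowsy (closed-eye) and
non-drowsy detections for the binarized descriptor path; the last two
columns compare accuracy of the baseline HOG path against the binarized
("advhog") path.  The binary descriptor holds up better than the baseline as
occlusion and low light get harder, and the Average row is the unweighted
mean over scenarios.

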