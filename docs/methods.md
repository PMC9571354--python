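# Methods

This note documents the models, parameters and design choices behind
`cishquant`, and what its synthetic-data experiments do and do not show.

## Synthetic scenes

The generator renders per-dye density maps and pushes them through the
forward Beer–Lambert camera model `I_k = Io_k · exp(−(Mᵀa)_k)`, the exact
model the color module inverts. Consequences worth knowing:

- **Exact invertibility.** On clean scenes (no blur, noise or 8-bit
  quantisation) deconvolution recovers the generator's density maps to
  machine precision; the 1e-6 round-trip tolerance in the tests is met with
  orders of magnitude to spare. Quantised uint8 tiles recover densities to
  roughly the quantisation level instead.
- **Geometry.** Nuclei are rotated ellipses with a ~1-px anti-aliased rim
  (density ramps linearly across the contour), so boundary-class learning is
  not trivially a hard edge. Dots are small anti-aliased disks whose
  densities add — two overlapping dots double the local density, which is
  what makes mass-based dot counting exact (see below).
- **Instance truth.** A nucleus is `singular` iff its mask touches neither
  another nucleus nor the image border, re-checked after all placements.
  Deliberately overlapping and border-truncated nuclei are placed at
  configurable fractions (defaults 0.15 / 0.10).
- **Conditions.** Default nucleus radii are 14–26 px so singular areas fall
  inside the 500–5000 px suitability gate; the per-nucleus signal means are
  Poisson(4) HER2 and Poisson(2) CEP17, a healthy complement. A
  `background_density` field adds uniform stromal counterstain uptake, used
  where realistic tissue coverage matters (quality calibration).
- **Determinism.** All randomness flows from `SceneSpec.seed`; identical
  specs are bit-identical. Layouts that admit no valid placement raise a
  placement error; protocol code (`workflows.generate_scenes`) skips such
  seeds deterministically.

What the generator does **not** emulate: tissue texture, stromal artifacts,
chromatic aberration, uneven illumination, or WSI-scale mosaics. Passing
tests on these scenes demonstrates the correctness of the pipeline's
mechanics and learnability of its target classes, not clinical performance.

## Quality gate

`Q = α + β·blurriness + γ·noise`, fitted by OLS with the MSE between
pristine and digitally degraded tiles as the response.

- **Blurriness** is the mean width of 1-D intensity edges pooled over
  horizontal and vertical scans; an edge is a gradient exceeding a
  threshold, and its width is the span of the monotone run through it
  (distance between the flanking local extrema).
- **Noise** averages the squared minimum center-to-neighbour difference
  over candidate pixels flagged by an unsharp mask (image minus 3×3 mean,
  cutoff one standard deviation of the response). Candidates on an edge of
  the *smoothed* image (gradient above the same threshold after 3×3
  averaging, which suppresses the noise itself) are removed: an isolated
  noise impulse differs from all eight neighbours while a structural edge
  shows up in the smoothed gradient. Without this explicit exclusion the
  statistic is dominated by the sharp rims and dot signals of rendered
  scenes and loses monotonicity in the noise level.
- **Calibration protocol** (`workflows.fit_quality_protocol`): four
  256×256 scenes with large (30–45 px) nuclei, 4-px dots, mild optical blur
  (σ=1) and diffuse stromal background; degradation grid factorial in blur
  {0, 1, 2} × noise {0, 6, 12} so the two predictors decorrelate; edge
  threshold 10 gray levels, at which the blurriness index keeps growing
  through σ≈3 instead of saturating (at threshold 20 the edges of a σ>2
  blur drop below threshold and the index collapses). The default threshold
  on the measuring functions remains 20 for sharp imagery; the calibrated
  `QualityModel` stores whichever threshold it was fitted with and `assess`
  reuses it.
- **Thresholds.** White level 200 (inclusive), white-fraction rejection at
  0.5. `Qth` has no universal value; by default it is set to the 95th
  percentile of Q over the calibration originals, so clean tiles pass by
  construction. Both gates short-circuit: a rejected tile produces a
  structured rejection record and no later stage runs.

## Color correction and deconvolution

Correction solves `P_input · W = [R,G,B]ᵀ` per pixel and re-projects with
the reference primaries; it is exactly linear up to the final clip to
[0, 255]. Two caveats are documented because they are easy to trip over:

- The transfer can push glass pixels out of gamut when a dye primary is
  nearly colinear with the glass color and the reference brightens it;
  clipping then breaks invertibility. Realistic mild drifts (the packaged
  `STAIN_SHIFTED_BASIS`) keep the transfer in gamut.
- At inference the input basis may come from the image itself
  (`estimate_basis` over dye-only masks) or from a stored scanner profile;
  both are supported, the pipeline config takes a basis path.

Optical densities use the natural logarithm (`m[d,k] = ln(Io_k/P_d[k])`);
any other base rescales all densities uniformly and cancels in the round
trip. Intensities are floored at 1 before the log; negative deconvolved
densities (out-of-gamut pixels) are clipped to zero and the clipped
fraction recorded. The nuclei channel is normalised to [0, 1] by a fixed
density ceiling (default 2.5 — a nucleus plus an overlapping nucleus or a
dot at the default basis), never a per-image maximum, so tiles of one
specimen remain mutually comparable.

## Segmentation

A NumPy encoder–decoder with skip connections: per level two 3×3
conv → batch-norm → ReLU blocks, 2×2 max pooling down, nearest-neighbour
upsampling and skip concatenation up, 1×1 softmax head with three classes.
Convolutions are lowered to GEMM via im2col in float32; the gradient of a
same-padded stride-1 3×3 convolution is itself a 3×3 correlation with the
flipped, channel-transposed kernel, so the backward pass reuses the same
machinery.

Defaults: depth 4, base 16 filters (~2.0 M parameters), Adam at learning
rate 1e-4, categorical cross-entropy, 30 epochs, batch size 1 (the classic
U-net regime — most parameter updates per epoch at fixed epoch count),
augmentation by horizontal/vertical flips and random zoom in [1.0, 1.1].
One seed drives initialisation, shuffling and augmentation; training is
reproducible bit-for-bit on a fixed BLAS. Batch norm with batch size 1
normalises over the spatial plane and keeps running statistics for
inference.

Desk-scale study conditions (`workflows.TRAINING_SCENE`): 30 training tiles
of 128×128 px with 5 nuclei each (radii 14–20 px, ellipticity ≤ 1.4,
default overlap/truncation mix), 10 held-out tiles for detection scoring.
Training takes ~5–6 minutes on one CPU core. Labels use boundary halfwidth
2 px (Euclidean disk erosion); instance recovery dilates inside-class
components with the same disk, so the label→instance round trip is exact on
isolated convex nuclei. Argmax ties resolve to the lowest class index.
A detection counts as a true positive when an accepted candidate matches a
ground-truth singular nucleus with IoU ≥ 0.5.

## Post-processing and scoring

Morphological opening (disk, radius 1) removes specks; if opening splits a
mask the largest component is kept. Circularity uses the Crofton-formula
perimeter estimator with 4 projection directions, which is close to
unbiased on rasterised disks (r=25 disk: perimeter 159.0 vs true 157.1,
circularity 0.975); border-counting or √2-weighted chain codes are biased
by several percent and would shift the 0.80 gate. The estimator is part of
the package contract — thresholds were interpreted with it and any
replacement would require re-calibration. Discrete circularity is capped at
1. The suitability score of an accepted nucleus equals its circularity; a
hook exists for an additional curvature term but none is defined.

## Signal counting and grading

`detect_signals` thresholds the CEP17 and HER2 density channels (default
0.3), labels 8-connected components and converts component mass to a dot
count (mass of one rendered dot as the unit) — additive densities make this
exact under dot overlap on clean scenes; on heavily degraded tiles it
degrades gracefully but is not a calibrated clinical detector.
`assign_signals` counts a signal for a nucleus only if every pixel of the
signal disk lies inside the closed nucleus mask; disks partially
overlapping the mask edge are excluded, and when accepted masks overlap
(possible after dilation) a contained signal goes only to the
highest-scoring nucleus. The ratio is computed from totals (ΣHER2/ΣCEP17),
the average copy from ΣHER2/n; groups are assigned by first match:
ratio ≥ 2 & avg ≥ 4 → 1 (Positive), ratio ≥ 2 → 2 (Positive),
avg ≥ 6 → 3 (Positive), avg ≥ 4 → 4 (Equivocal), else 5 (Negative).
Fewer than 20 nuclei or zero total CEP17 raise typed errors.

## FISH mode

Fluorescence tiles are bright-on-dark with negligible dye cross-talk, so
the pipeline substitutes the inverted grayscale intensity image for the
deconvolved nuclei channel and skips color correction/deconvolution;
segmentation, filtering and counting are unchanged.

## Known limitations

- Clinical performance numbers (true/false positive rates on slides,
  pathologist concordance, runtimes) are not reproducible here; all
  reported quantities are properties of the synthetic study conditions.
- The noise index assumes impulse-like noise; structured noise (banding,
  compression) is not modelled.
- The watershed-free design rejects merged nuclei rather than splitting
  them, by construction.
- The linear color correction operates in RGB space and is exact only for
  pixels inside the dye gamut; extreme stain drift can clip.
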