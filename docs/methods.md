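# Methods

## Problem

Camera-based electronic insect traps (e-traps) photograph their interior once a
day and report to a server. Running the analysis on the device itself — an
ESP32-class microcontroller — keeps the radio mostly silent and the battery
alive for weeks, but constrains the model to well under a megabyte. `trapcount`
implements that pipeline at desk scale: a synthetic scene generator with exact
ground-truth counts, a compact counting-by-regression CNN, post-training 8-bit
quantization, the counting-accuracy metric α, and a duty-cycle/battery
simulator.

Counting is posed as scalar regression (image → real-valued count), skipping
detection, segmentation and species identification. A regression head is far
smaller than detector architectures and is more tolerant of partially
overlapping insects; the price is that the output must be rounded and can be
wrong without any notion of *where* the error is.

## Synthetic scenes with exact labels

Hand-tagging thousands of trap photos is impractical, so labeled scenes are
*composed*: sprites (insect cutouts with a transparency mask) are pasted onto a
trap-floor background at uniform random rotations in [0°, 360°) and
rejection-sampled anchor positions, a uniform count of 0–6 per image. The count
label is exact by construction and encoded in the filename
(`{split}_{id:06d}_count{Mc}.png`).

Placement enforces **zero mask overlap** plus a 1-px separation margin
(checked on 1-px-dilated binary masks). Real sticky traps only make large
overlaps unlikely; the zero-overlap tightening buys exact label fidelity — an
oracle that recounts connected components of `image − background` recovers the
label exactly when illumination jitter is off, and the test suite relies on
that.

Sprites come from two sources behind one interface:

* **Real cutouts** — PNG/JPEG photos; `extract_cutout` recovers the mask as the
  largest connected component of `|photo − background| > 0.08` after 3×3
  binary closing. Alpha is hard (binarized at 0.5) so overlap checks are exact
  set operations.
* **Procedural sprites** — the default; an elliptical body (length 12–60 px at
  240 px scene scale, aspect 2–5, scaled proportionally for smaller scenes),
  0–8 elbowed polyline limbs rooted inside the body, optional lighter wing
  lobes, luminance 0.05–0.40 against ~0.82 floors. They emulate the *diversity*
  of insect body plans, not any species. Every sprite is a single connected
  component, deterministic in its seed.

A bank of 100 sprites is partitioned 70/30; test scenes are composed
exclusively from the 30 held-out sprites, so test accuracy measures
generalization to unseen insect shapes, not memorization.

The background model is one smooth-textured gray floor per dataset (base 0.82,
±0.04 low-frequency texture) with per-image brightness jitter (±5%) and faint
smooth noise, emulating "backgrounds that differ slightly". What the generator
does **not** emulate: debris, insect decay, moving insects, shadows, focus and
exposure variation, or insect overlap. Passing tests therefore demonstrate the
pipeline's correctness and the method's behavior under controlled conditions,
not field performance on real trap photos.

The default dataset mirrors the reference database: a 14,000-image training
pool (2,000 per class 0–6) split 70/30 into train/validation per class at the
image level, plus 1,400 test images (200 per class). Whether the original
70/30 split was at image level is not documented; image-level is our choice.
Scenes are deterministic functions of `(config, seed)`: the manifest stores
metadata and per-scene seeds, and any scene can be regenerated bit-for-bit on
demand (an overcrowded layout retries with a salted seed, changing placements
but never the background or the count label).

## The counting network

A four-block stack of 3×3 conv (stride 1, same padding) → ReLU → 2×2 max-pool,
channel widths (16, 32, 64, 128), then a **global sum pool** and a single
linear unit; ~97k parameters at 240×240×1 input. Design notes:

* **Sum, not average, pooling.** A count is an extensive quantity — the
  spatial integral of an insect-density map. With average pooling the head
  weights must grow ~`H·W`-fold to span the 0–6 output range, which Adam at
  lr 0.001 cannot deliver inside a short training budget; with sum pooling the
  target scale is reachable immediately. (Measured on the reduced-scale study:
  an average-pool head plateaus around mean α 0.92 where the sum-pool head
  reaches ≥ 0.95.)
* **Linear head, no output activation.** Negative raw outputs are legal and
  handled at rounding; clamping inside the network would distort MSE gradients.
* **Fixed input centering.** The network subtracts 0.5 from its [0, 1] inputs
  (folds into the input zero-point on integer engines), and the head bias
  starts at 3.0, the count-range midpoint — both purely conditioning choices.
* Weights are Glorot-uniform from a seeded generator; two builds from the same
  config are bit-identical.

Training: MSE loss, Adam (lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-7), batch size 32,
up to 240 epochs full scale. Augmentation on training inputs only, each applied
independently: horizontal/vertical flips (p 0.5 each), rotation (p 0.5, ±20°),
zoom (p 0.2, factor 0.8–1.2). Rotation expands the canvas and resizes back so
no insect leaves the frame — the count label survives augmentation by
construction (magnitudes ±20° and 0.8–1.2 are our defaults; only the
probabilities are prescribed). Validation mean α (after rounding) is monitored
each epoch; training stops at the epoch cap or after `patience` epochs without
improvement, and the best-validation weights are restored.

The whole network — forward, backward, Adam — is plain float32 NumPy
(convolution as k² shifted GEMMs). At this parameter count framework overhead
would dominate the arithmetic, and the implementation doubles as an explicit
reference for the quantizer.

### Reduced ("desk") scale

The full study (14,000 scenes at 240×240, 240 epochs) needs a GPU-hour; the
reduced configuration reproduces the behavior on one CPU in minutes: 64×64
scenes with proportionally scaled sprites, 300 scenes/class pool (split 70/30)
and 50/class test, a three-block (16, 32, 64) stack (~23k parameters), ≤ 30
epochs, patience 8. The three-block variant generalizes better across held-out
sprite identities at this scale than the four-block one, whose extra capacity
overfits the 70 training sprites. Mean test α of the pinned-seed run exceeds
0.95, mirroring the full-scale behavior; exact per-class accuracies depend on
which sprites the partition holds out and are not reproduction targets.

## Rounding and the α metric

`Ac = max(0, round-half-away-from-zero(ŷ))`. Counting accuracy per image:

    α = 1 − |Mc − Ac| / max(Mc, 1)

As printed, the formula divides by Mc and is undefined for empty scenes; the
`max(Mc, 1)` convention reduces to exact-match for the background class and is
continuous with Mc = 1. α is *not* floored at zero (a wild miscount scores
negative); the exact-match rate is reported alongside. The reported mean is the
unweighted per-image mean, which on a balanced test set equals the mean of
class means.

## 8-bit post-training quantization

Weights: per-tensor symmetric int8 (scale `max|W|/127`). Activations:
per-tensor asymmetric uint8 with ranges calibrated by running 128
representative training images through the float network (min/max per tensor).
Biases: int32 at scale `s_weight · s_input`. Input/output tensors stay float32
at the interface. Inference evaluates on the exact dequantized grid, i.e. it
simulates what an integer engine with float I/O fallback computes, and the
serialized artifact (int8/int32 tensors + scale metadata in a flat container)
is measured for the size budget: ≤ 0.55 MB for the full-resolution model
(actual: ~0.1 MB; the float32 serialization is ~0.39 MB, a >3.5× reduction).

**The calibration sample must span all count classes.** Ranges calibrated on
empty scenes clip the activations of crowded scenes and collapse accuracy
(measured: mean α drop ~0.2 with a class-0-only sample vs ~0.002 with a seeded
uniform sample over the training split). Every entry point draws calibration
images with a seeded uniform choice for this reason.

## Duty cycle and battery life

The deployed trap wakes once per day: load model → capture (night, flash) →
infer → upload *iff the rounded count differs from yesterday's* (the first
observation always uploads — our convention for a defined initial state) →
store locally → deep sleep. Upload transport is an injected interface; the
default mock records JSON + PNG payloads.

Energy model: the active window displaces sleep within the 86,400-s day,

    daily_mAh = [I_sleep · (86400 − n·T_active) + n·Σ(Iᵢ·tᵢ)] / 3600
    days      = capacity_mAh / daily_mAh

with `n` cycles/day (default 1). It is a maximum-consumption scenario (an
upload every day); it is linear in every current and monotone decreasing in
currents and cycle count. Profiles for ESP32-CAM, Raspberry Pi 4, and Coral
(CPU and TPU) ship as YAML. The ESP32 figures (sleep 6 mA; 180 mA/2 s capture,
85 mA/51 s inference, 150 mA/3.5 s store+upload, 70 mA/6.5 s housekeeping;
2×3,350 mAh) give 145.5 mAh/day → **46.1 days**. The published per-phase cells
are internally inconsistent with their printed 5,595 mA·s total (the weighted
sum is 5,675) and with the quoted ~50-day lifetime; the estimator implements
the formula and we report the arithmetic as computed.

The deployment simulator renders the trap floor day by day with insects
accumulating in place (sticky traps: a monotone non-decreasing schedule), runs
the daily cycle against any counter (trained model or oracle), and accounts
energy additively.

## Numerical and degenerate-input conventions

* All randomness flows from one run seed through `numpy` `SeedSequence`
  spawning; scene seeds are stored in the manifest; derived seeds stay below
  2³¹.
* Sprite rotation uses bilinear resampling with canvas expansion; the rotated
  alpha is re-binarized at 0.5 and only the largest connected component kept
  (resampling can shave sub-pixel fragments off 1-px legs).
* Partition rounding: `round(n·fraction)` to train, ties toward train (matches
  70/100 exactly and errs toward more training data). A partition that would
  empty either side is an error.
* An overcrowded scene (no disjoint anchor after 200 attempts per sprite) is an
  error and is re-laid-out with a fresh salted seed — never silently
  mislabeled.
* Mc = 0 in α uses the `max(Mc, 1)` convention above; non-finite predictions
  are errors, not silently clipped.
* Coordinates are 0-based, row-major, top-left origin; images are 8-bit
  grayscale PNG on disk, float32 [0, 1] in memory.

## Known limitations

* Procedural sprites are silhouettes with simple texture; nothing here
  validates species-level appearance, debris robustness, or real camera noise.
* The quantized path simulates integer inference on the dequantized grid; it
  does not bit-match any particular integer kernel implementation.
* The α metric rewards near misses on crowded scenes (|error|/Mc) and is harsh
  on singletons; comparisons across class distributions need the per-class
  table, not just the mean.
* Training reproducibility is bit-exact only on a fixed BLAS/platform;
  across platforms expect small numerical drift.
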