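# Methods

## The transform

The package implements a second-generation bandelet construction: the
geometric adaptation operates on the detail subbands of a separable 2D
DWT, not on raw pixels. An image is first decomposed with an orthogonal
wavelet (`db2` by default, `periodization` boundary handling so that
orthonormality and Parseval hold exactly and coefficient counts equal
pixel counts for power-of-two shapes). Each detail subband (LH, HL, HH per
level) is zero-padded to the smallest enclosing power-of-two square — the
padding is recorded and stripped on inversion — and covered by a dyadic
quadtree searched bottom-up.

Every node evaluates two options. *Direct* encoding scores the block under
each candidate of a finite flow dictionary: `NO_FLOW` leaves the block in
its separable form; a slope c′ reorders the block's positions by the
warped key x₂ − c′·x₁ (ties broken by ascending x₁) and applies a
full-depth 1D orthogonal DWT along the reordered sequence. The reordering
is a permutation and the 1D transform is orthogonal and periodised, so
every leaf operation — and hence the whole transform — is exactly
invertible; no interpolation or resampling is involved anywhere.
*Subdivision* replaces the block by its four quadrants at a fixed overhead
of λT². The dynamic program `L₀ = min(L_direct, L̃)` returns the global
optimum over all admissible quadtrees (verified against explicit
enumeration in the tests).

Block cost is `distortion + λT²(R_G + R_B)`: distortion is the squared
error left by hard thresholding at T (identical in coefficient and pixel
domain by orthonormality), R_B counts coefficients with |c| > T (strict
inequality, used consistently everywhere a survivor is counted), and R_G
is the dictionary index width `ceil(log2(dictionary size))` for a flowed
block or 1 for `NO_FLOW`. Cost ties prefer `DIRECT` over subdivision and
`NO_FLOW` over flows, then smaller |c′|, then the negative sign — the
simplest geometric model wins and output is deterministic.

### Parameters

| parameter | default | meaning and rationale |
| --- | --- | --- |
| `wavelet_name` | `db2` | orthogonal 4-tap Daubechies pair; any orthogonal PyWavelets name works |
| `levels` | 2 (transform), 1 (feature tensors) | decomposition depth; one level suffices for the four feature channels |
| `T` | 30 | significance threshold on the 8-bit intensity scale (images are 0–255 floats) |
| `lam` (λ) | 4.0 | Lagrangian price of one rate unit, in units of T² (see below) |
| `n_directions`, `max_slope` | 16, 2.0 | flow dictionary: 16 uniform slopes in [−2, 2] plus a forced 0 plus `NO_FLOW`; the slope multiset is exactly closed under negation |
| `min_block` | 4 | smallest quadtree leaf side; leaves at this size are forced DIRECT |

**Why λ = 4.** With per-survivor significance counting, λ = 1 makes one
rate unit (λT²) exactly equal to the worst-case distortion a discarded
coefficient can carry (T²). At that break-even point, trades that lower
distortion by *raising* the significant count are cost-neutral, and on
speckled inputs noise decides them — the optimiser then sometimes returns
representations *less* sparse than the plain wavelet, defeating the
purpose of the construction. Setting λ = 4 makes rate strictly dominate:
an extra surviving coefficient must buy more distortion reduction than
several discarded coefficients can carry, so the optimum is sparsity-first
and the bandelet is reliably at least as sparse as the wavelet baseline at
equal T. λ remains configurable for users who want a
distortion-oriented operating point.

**Warp resolution limit.** On an h×w block, two slopes closer than
1/(h−1) can induce the same permutation, in which case they are
indistinguishable by construction and the tie rules pick the smaller
|slope|. Flow recovery on 8×8 blocks therefore cannot separate the finest
dictionary steps; at 16×16 all 17 default slopes are distinguishable.

## Feature tensors

`extract_bandelet_tensor` resizes the image to a working resolution
(default 512, bilinear), runs the bandelet transform at one level, and
materialises four coefficient-domain maps: the approximation grid (A) and
the three level-1 detail grids (H = LH, V = HL, D = HH) with each leaf's
bandelet coefficients scattered back to the leaf's own grid positions in
warped-rank order. These are coefficient maps, not partial
reconstructions: they preserve the sparsity pattern the transform
produces. Each map is resized to the classifier input (default 224) and
stacked. One decomposition level is used because the channel set is fixed
at four regardless of depth; deeper transforms add cost without adding
channels.

Normalisation is per-channel z-score with *population* standard deviation
computed over all training-split pixels; a degenerate (constant) channel
gets σ clamped to 1. Statistics are fitted on the training split only and
applied unchanged to validation data; re-normalising an already-normalised
tensor is rejected, which together makes silent leakage impossible.

## Data program

The preprocessing chain reproduces the standard recipe for a small
imbalanced ultrasound collection. SMOTE synthesises minority images as
`x_i + u·(x_nn − x_i)` with u ~ U(0,1) and x_nn one of the k = 5 nearest
minority neighbours in flattened pixel space (sklearn `NearestNeighbors`
backs the query). Balanced combination takes the first `per_class` items
of each class, the majority truncated in stable input order.

Augmentation grows the balanced set to a target count. Each new item
applies, independently with probability 0.5: brightness scaling
U[0.8, 1.2], horizontal flip, rotation U[−15°, +15°] with edge
(nearest-value) fill, and height scaling U[0.9, 1.1] with edge fill; every
output is resized to a fixed square (default 512) and clipped to [0, 255].
Base images are cycled per class with a largest-deficit interleave so
class proportions stay within one item at every prefix. The ±15°, 0.8–1.2
and 0.9–1.1 ranges are the package's defaults for "mild, label-preserving"
ultrasound perturbations.

The 80/20 split is stratified with `floor`-based arithmetic (2048 → 1638 /
410), allocated across classes by largest remainder. By default
augmentation precedes the split — the reference protocol — which means
augmented siblings of one base image can land on both sides of the split;
the optional `split_before_augment` mode splits the 56 base images first
and augments each side independently, the methodologically safer variant
for honest generalisation estimates.

## Classifier

The test backbone is a 3-block CNN written directly on numpy (3×3
convolutions with ReLU, 2×2 average pooling, channels 8/16/32, flatten +
linear softmax head sized lazily from the input resolution), trained by
plain mini-batch gradient descent θ ← θ − α∇L on the cross-entropy
(α = 0.05, batch 16). Fine-tuning follows the transfer-learning contract:
the convolutional base is bit-frozen for the first `freeze_epochs`
(default 3; only the head updates), then unfrozen at half the learning
rate. An optional mixed objective λ_mix·L_source + (1−λ_mix)·L_target is
supported when a source batch stream is provided; the default λ_mix = 0 is
pure target fine-tuning. Everything is deterministic given the config
seed. The backbone interface (`train_classifier(train, val, config)`,
`model.predict`) is pluggable, so a large pretrained network can be
substituted without touching the pipeline.

Metrics treat malignant (label 1) as positive. Ratios with zero
denominators are reported as absent (`None`), never as 0. Fold statistics
use linear-interpolation quartiles and population variance; repeated
stratified k-fold cross-validation is backed by sklearn's
`StratifiedKFold` with per-repeat seeds.

## Synthetic phantoms

The generator emulates B-mode thyroid ultrasound at the level the pipeline
needs: a smooth tissue background (depth gradient plus blurred texture),
an embedded hypoechoic nodule whose radius is modulated by a random-phase
harmonic series, and multiplicative speckle `x·(1 + s·η)` with η a
zero-mean unit-variance shifted log-normal field (positive skew, the
standard proxy for coherent-interference noise; s = 0.18 by default).
Class geometry encodes the clinical cues: benign nodules are smooth
(amplitude ≤ 0.03·radius, ≤ 2 harmonics) and wider than tall; malignant
nodules are irregular (amplitude ≥ 0.12·radius, ≥ 5 harmonics) and taller
than wide. The classes overlap in echogenicity but are separable by
boundary geometry — which is exactly what the bandelet features are
designed to capture. The default dataset is 14 benign / 62 malignant,
matching the imbalance of public thyroid B-mode collections.

What the phantoms do *not* model: acoustic shadowing and enhancement,
calcifications, probe-dependent point-spread anisotropy, out-of-plane
motion, and annotation noise. Tests passing on phantoms therefore
demonstrate that the machinery is correct and that the geometric cue is
recoverable — not that any particular clinical accuracy would be attained
on real ultrasound.

## Problem sizes used by the tests and the acceptance script

Round-trip, oracle-equivalence and anisotropy checks run on 64×64 images /
8×8 subbands where enumeration is exhaustive. The count-trace run uses
64×64 phantoms with augmentation output 128 — the stage counts are
independent of image size, so the 512 default is exercised elsewhere and
the trace stays quick. The learnability check uses 200 phantoms at 64×64,
feature tensors at 32×32 with an 8-direction dictionary, and 20 training
epochs; its label-permutation twin must stay within the binomial chance
band. These sizes are the package's own test-design choices and are
recorded here so they can be scaled up verbatim.

## Numerical choices and degenerate inputs

- Boundary mode `periodization` everywhere; full-depth 1D transforms are
  taken to the deepest level the dyadic structure of the length allows
  (depth 0, i.e. identity, for odd lengths and 1×1 blocks).
- Hard thresholding keeps strictly `|c| > T`; the coarsest LL is never
  thresholded.
- Zero-padding of subbands is recorded as the unpadded shape and stripped
  after inversion; padded zeros never count as significant.
- Constant blocks tie all flow candidates at zero distortion; the tie
  rules return `NO_FLOW`, so constant images produce all-DIRECT,
  all-NO_FLOW trees with zero significant coefficients.
- `σ = 0` feature channels are clamped to 1; empty datasets, mismatched
  shapes, out-of-range parameters and unknown config keys are rejected
  with named diagnostics.
- Per-stage seeds derive from the global seed by SHA-256 of
  `"{seed}:{stage}"`, truncated below 2³¹.

## Known limitations

- The per-leaf flow is a constant slope (linear flow); curvature within a
  leaf is handled by quadtree refinement, not by higher-order flow models.
- R_G/R_B are significance-unit proxies, not an entropy-coded bit stream;
  the package does not do compression or rate control.
- The full-depth 1D transform amplifies a leaf's DC by √n, which can push
  block means above T; this is priced into the cost and handled by the
  optimiser, but it makes per-leaf counts depend on block size.
- The numpy CNN is deliberately small; it establishes the training
  contract and the learnability of the fixture, not state-of-the-art
  accuracy.
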