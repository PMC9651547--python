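# Methods

## Model

The classifier is a four-stage hierarchical transformer encoder with
convolutional machinery in every block. An input image (H=W divisible by
32, RGB or grayscale) passes through:

1. **CTE**: conv 3×3, stride 1, 16 output channels, padding 1; BatchNorm;
   ReLU; maxpool 3×3, stride 2, padding 1. Output is a half-resolution,
   16-channel map.
2. **Four stages**, each a 2×2 stride-2 feature-embedding convolution
   (channels 24/32/48/64) followed by a stack of encoder blocks (layout
   [2,2,4,2]). Feature-map sides are input/4, /8, /16, /32.
3. **Head**: global average pooling, layer norm, one dense layer to the
   class scores; softmax for probabilities. Ties in the argmax resolve to
   the lowest class index.

An **encoder block** is the pre-norm residual composition
`x ← x + CPSA(LN(x)); x ← x + LFFN(LN(x))`. Pre-normalization was chosen
for stability when training from scratch on very small datasets; the
residual contract is testable directly (zeroing the two output
projections makes the block the identity).

**CPSA.** The shared key/value matrix is
`S = Flatten(PW(DW(x, s, s)))`: a depthwise s×s stride-s convolution
(s = reduction rate, [8,4,2,1] per stage; adds s²·C weights) followed by
a pointwise 1×1 map, which *is* the shared projection — sharing one C×C
map between key and value instead of two is what halves that part of the
attention parameters. Per head, `softmax(Q·Sᵀ/√d_head)·S`, heads
concatenated and linearly mixed. The query is not convolutionally
reduced, so the output token count equals the input's. Two switches
cover the genuinely underdetermined parts of the design: `project_q`
(default on — a learnable dense map on Q; a pure reshape cannot change
basis and the standard attention formulation includes it) and `share_kv`
(default on; off instantiates a separate pointwise value branch, adding
exactly C²+C weights). With s=1, sharing off, and an identity depthwise,
the block reduces to textbook dense multi-head attention — the test suite
pins this against an independently coded oracle at 1e-5.

**LFFN.** On the 2-D-reshaped tokens (side = √N; non-square token counts
are rejected): depthwise k×k → pointwise 1×1 (C→C) → pointwise expand
(C→eC) → GELU → depthwise k×k at eC → pointwise reduce (eC→C) → flatten.
Defaults e=4, k=3, padding (k−1)/2 (forced by shape preservation). The
first stage is a full depthwise-separable convolution (depthwise plus its
pointwise half) rather than a bare depthwise; the second depthwise stands
alone because the expansion/reduction 1×1s around it already provide the
pointwise mixing. The only activation is the GELU after the expansion —
the sandglass convention of keeping the wide ends linear. `k=1` removes
all spatial mixing (verified as a per-token locality property).

**Attention/FFN baselines for ablation** are a dense QKV multi-head
attention and a two-layer dense FFN with the same widths; further
ablation axes are the stage-1 position embedding (default off — the model
is resolution-agnostic without it), layout, heads, reduction rates, and
the LFFN kernel.

## Parameter accounting

Weights are float32. The census walks every learnable tensor exactly
once (BatchNorm running statistics are buffers, not weights) and defines
"serialized megabytes" as `count × 4 / 2²⁰`. The default 21-class model:
305,117 weights = 1.1639 MB. A closed-form census oracle in the tests
recomputes this from the architecture arithmetic. The published size of
this architecture family is printed inconsistently across sources (1.3
and 1.18 MB for the same model), so sizes should be compared within a
counting-convention tolerance rather than exactly; our count sits within
that band. Checkpoints are `.npz` archives of the named float32 arrays
plus the embedded config JSON; round-trips are bit-exact.

## Numerical core

No deep-learning framework is used. `htem.autodiff` is a small
reverse-mode tape over NumPy arrays with fused kernels for softmax,
layer/batch norm, convolutions (direct loop over the ≤8×8 kernel
positions, each a batched matmul — efficient at these kernel sizes),
max-pooling (argmax scatter) and cross-entropy. Every operation's adjoint
is verified against central finite differences in float64. Weight
initialization: truncated normal (σ=0.02, clipped at 2σ) for dense
matrices, fan-out-scaled normal for convolution kernels, ones/zeros for
norms; all generators are explicitly seeded, and training is bitwise
reproducible for a fixed (config, seed, data) triple.

## Training protocol

Defaults follow the reference protocol: Adam (β=0.9/0.999), learning rate
0.002, batch size 32, 100 epochs, 224×224 inputs, cross-entropy on the
pre-softmax scores. The optimizer and loss were not pinned down by the
protocol source; Adam with cross-entropy is the field default and SGD is
available as a config option. No learning-rate schedule is used (none is
specified). When a validation split exists, the weights of the best
validation-accuracy epoch are restored at the end of training.

Preprocessing resizes the shorter image side to the target side and
center-crops ("cropped to 224×224" is read aspect-preservingly; a pure
crop would discard most of larger images), then scales intensities to
[0,1]. Geometric augmentation (rotations 90/180/270, up-down and
left-right mirrors; exactly 6× the input) is applied to the training
split only — whether evaluation splits should contain transformed copies
is unspecified in the protocol, and keeping evaluation untransformed is
the conservative choice; a switch exposes the alternative. Splits are
stratified per class with largest-remainder rounding (only global
fractions 37.5/25/37.5 are specified).

**Noise evaluation** corrupts held-out images before preprocessing:
salt-and-pepper sets exactly `round(amount·H·W)` pixel locations to 0 or
1 (equal probability), Gaussian adds N(0, σ²) per channel with clipping.
Magnitudes are unspecified in the protocol; the defaults amount=0.05 and
σ=0.05 on the [0,1] scale produce the mild accuracy drops characteristic
of this evaluation, and both are configurable.

**One-vs-rest protocol**: each class in turn is relabelled positive
against the rest, a fresh two-class model is trained per version, and AP
is computed from the positive-class scores on the validation split; mAP
is the arithmetic mean over versions.

## Metrics

Macro averaging (per-class, unweighted) for precision/recall/F1 — on a
class-balanced evaluation set macro recall provably equals accuracy,
which is the signature the reference tables display. Classes with a zero
denominator contribute 0 with a warning rather than NaN. AP is
*interpolated* average precision: `(1/M) Σᵢ max_{r ≥ rᵢ} precision(r)`
over the M positives, with descending-score ordering and ties kept in
original order; all-point interpolation was chosen (an 11-point variant
cannot be ruled in or out from the formula alone) and an exhaustive
PR-curve oracle pins the semantics to 1e-9 in the tests.

## Synthetic data

The generator emulates the regime of a small balanced electron-microscopy
collection — by default 21 classes × 40 images — where classes differ
mainly in organism morphology. Six shape archetypes (ellipsoid, rod,
rayed star, spiral, flagellated blob, ring) are cycled with per-class
size ranges, texture frequencies and background intensities, each image
randomized in pose, scale and noise; datasets are a pure function of
their spec (verified by pixel digest). It does **not** emulate real
microscopy's staining variation, occlusion, debris, inter-class
confusability or annotation noise — so passing tests demonstrate the
pipeline's correctness and the architecture's trainability, not
field-level accuracy. Discriminability is held to a weak oracle (a
pixel-mean nearest-centroid rule must beat chance), keeping the task
nontrivial for honest learning checks.

## Problem sizes in the test suite

The tests exercise the full pipeline at reduced scale as the package's
own verification budget: gradient checks on ≤8×8 maps, end-to-end
training on 2–4 classes at 32–64 px, and the learning-sanity check
(default model, 64 px, 4 classes × 30 images, 30 epochs, 3 seeds, ≥90%
median training accuracy). The full 224 px / 21-class configuration is
exercised for construction, census, and single forward passes.

## Known limitations

* CPU-only and NumPy-bound: a full 224 px / 100-epoch training run is
  hours, not minutes; the architecture itself is small enough that this
  is usable but not fast.
* Non-square inputs and sides not divisible by the stride ladder are
  rejected rather than padded, keeping shape contracts exact.
* With the default channel widths (24/32/48/64), head counts must divide
  the width — e.g. 3 heads per stage is not constructible, so ablation
  grids over heads use divisors.
* No pretrained weights, quantization, or deployment export.
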