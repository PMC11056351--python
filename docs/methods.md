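# Methods

## The model

`scmpmixer` implements a hybrid image classifier for single-cell blood
smear crops (white blood cell subtyping) that combines convolutional
patch mixing with windowed self-attention. The network has three stages.

**Stage 1 — multipath ConvMixer (MPCM).** Three ConvMixer branches run in
parallel at patch sizes p = 2, 4, 8. Each branch starts with a patch
embedding — a convolution with kernel = stride = p and h = 128 filters,
followed by GELU and batch normalization — and continues with `depth` = 4
mixer blocks:

    z' = BN(GELU(DepthwiseConv_3x3(x))) + x
    z  = BN(GELU(PointwiseConv(z')))

The residual connection wraps the depthwise stage only; the depthwise
convolution uses "same" zero padding so the addition is shape-consistent.
The three branch outputs (input/2, input/4, input/8 on a side) are brought
to the finest grid with parameter-free nearest-neighbour upsampling
(strides 2 and 4) and fused by element-wise addition, giving a
(input/2, input/2, 128) feature map.

**Stage 2 — multipath Swin (MPST).** Two token branches are extracted from
the fused map at effective patch sizes 4 and 8: a 1x1 convolution first
reduces the channel count to k = 256 / p_eff², then non-overlapping
p_eff x p_eff patches are flattened, so every token is 256-wide regardless
of p_eff. At the default 224-pixel input this yields 28x28 = 784 and
14x14 = 196 tokens. Each token grid passes through Swin attention cycles:

    z_hat      = W-MSA(LN(z_in))     + z_in
    z          = MLP(LN(z_hat))      + z_hat
    z_hat_next = SW-MSA(LN(z))       + z
    z_out      = MLP(LN(z_hat_next)) + z_hat_next

W-MSA applies multi-head self-attention inside non-overlapping 7x7 token
windows; SW-MSA first rolls the grid by 3 tokens along both axes and masks
attention between tokens that originate from different pre-shift regions
(additive −1e9 bias before the softmax), the standard cyclic-shift
realization that preserves the token count. The MLP is
FC(256) → GELU → dropout → FC(dim) → dropout. The two branch outputs are
concatenated along the token axis: 784 + 196 = 980 tokens of width 256.

**Stage 3 — head.** Global average pooling over the token axis, a fully
connected layer with one output per class, and a softmax. Training
minimizes categorical cross-entropy, L = −Σ_k Y_k log P_k (batch mean).

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| input size | 224 px | forced by the 112x112x128 stage-2 input together with the p=2 branch producing input/2 |
| MPCM patch sizes | 2, 4, 8 | finest branch fixes the fused grid |
| filters h | 128 | pointwise width of every mixer block |
| depth | 4 | mixer blocks per branch |
| depthwise kernel | 3x3 | "same" padded |
| MPST token grids | 28, 14 | equivalently effective patch sizes 4, 8 |
| token width | 256 | invariant across branches by k = 256/p_eff² |
| window / shift | 7 / 3 | 7 divides both default grids; shift = ⌊7/2⌋ |
| heads | 4 | head dim 64 at width 256 |
| MLP width | 256 | |
| dropout | 0.1 | MLP only; 0 in the desk preset |
| cycles per branch | 2 | see open choices below |
| optimizer | Adam, lr 1e-4, β 0.9/0.999, eps 1e-7 | batch 16, 100 epochs at full scale |
| splits | 70/15/15 | stratified, seeded; presplit mode carves 15% of a provided train set for validation |

## Design choices where the design was open

- **MPST patch sizes.** The two printed token-matrix shapes (784x256,
  196x256, concatenating to 980x256 from a 112-wide map) fix the effective
  patch sizes at 4 and 8; the package parameterises the stage by the token
  grids and derives p_eff = (input/2)//grid. The `mpst_grids` field makes
  the alternative reading (patch sizes 2 and 4) runnable as configuration.
- **MPST on other spatial sides.** The ablation variant that applies the
  multipath Swin stage directly to a 1x1-conv-lifted image reuses the same
  effective patch sizes rather than the same grids; this keeps
  k = token_dim/p_eff² a positive integer at every input scale and means
  the token count, not the token width, varies with the input side.
- **Attention cycles per branch.** Applying the Swin operation "twice" is
  read as two full W-MSA/SW-MSA cycles per branch (each cycle already
  contains both window passes); `cycles_per_branch` exposes the
  single-cycle reading.
- **Single-branch attention variants.** The attention-only ablation uses
  one branch on the raw image at the largest effective patch size
  (28x28 grid at full scale); the MPCM+single-attention variant uses the
  finer branch (grid 28 on the fused map).
- **Upsampling and fusion.** Nearest-neighbour upsampling (parameter-free)
  and element-wise addition; concatenation was rejected because the fused
  map must keep 128 channels for stage 2.
- **Normalization details.** BatchNorm per channel, momentum 0.9,
  eps 1e-5, running statistics in inference; LayerNorm over the embedding
  axis, eps 1e-5. GELU is the exact erf form. Softmax is stabilized by
  max-subtraction; cross-entropy clamps probabilities to [1e-7, 1], so a
  zero probability at the true class gives a large finite loss.
- **Initialization.** Truncated normal (std 0.02, resampled beyond 2 std)
  for all weights, zeros for biases; fully seeded. Argmax prediction
  breaks ties toward the lowest class index.
- **Checkpoint selection.** The snapshot with the highest validation
  accuracy is retained (no early stopping, no LR schedule, no
  augmentation; shuffling is per-epoch and seeded).

## Implementation

No GPU framework is used: layers, windowed attention, manual
backpropagation and the Adam optimizer are implemented in NumPy
(`scmpmixer.nn`), with float32 arithmetic and BLAS-backed matrix
multiplies (patch embedding via space-to-depth + matmul, depthwise
convolution as k² shifted multiply-accumulates). Every analytic gradient
is validated against finite differences and against closed-form oracles
in the test suite. scikit-learn appears only as an independent metrics
oracle in tests.

## Evaluation conventions

Per-class metrics are one-vs-rest: the confusion matrix (rows = true,
columns = predicted) collapses to TP/FP/FN/TN per class, from which
Acc = (TP+TN)/total, Pr = TP/(TP+FP), Re = TP/(TP+FN) and the harmonic
F1 are computed in percent. The macro row is the unweighted mean over
classes, computed on unrounded values; display rounding is half-up to two
decimals. Because one-vs-rest accuracy credits true negatives, the macro
Acc exceeds pooled (trace/total) accuracy whenever any off-diagonal mass
exists and there are more than two classes. Zero denominators report 0
with a warning.

## Synthetic data

The generator emulates the class-conditioned morphology that separates
leukocyte subtypes in stained smears: nucleus lobe count (1–5 blobs),
nucleus/cell area ratio (driven to its target by bisection on the blob
radius, so the measured ratio tracks the parameter monotonically), cell
and nucleus stain hues, size jitter, and additive Gaussian background
noise clipped to [0, 1]. Presets mirror the 4-, 5- and 8-class public
dataset structures (`wbc4`, `wbc5`, `wbc8`), and `easy3` is a deliberately
well-separated 3-class set used for learning-capability checks. What the
generator does **not** reproduce: real stain texture, cytoplasm granules,
touching cells, illumination gradients, or class imbalance. Passing tests
on synthetic data therefore demonstrate that the architecture, gradients,
pipeline and metrics behave as specified — not that full-scale headline
accuracies on the public datasets are reproduced, which would require the
external images and long GPU training and is out of scope.

## Problem sizes used in the shipped tests

The default test configuration is the desk preset: input 112, filters 32,
depth 2, token grids 14/7, token width 64, MLP width 64, no dropout,
30 epochs at lr 1e-3 (a standard Adam rate for a ~200-step schedule).
The learning-capability check trains the full variant on `easy3`
(40 images/class, stratified 70/15/15) and requires ≥ 90% validation
accuracy within 30 epochs; the ablation driver runs all seven variants
for 2 epochs on 12 images/class, which exercises the wiring without
asserting relative orderings (at that scale they are noise). Full-scale
(224/128/256) forward passes are exercised structurally, including the
980-token concatenation.

## Known limitations

- CPU-only NumPy training is practical at desk scale; the full 224-pixel
  configuration trains only slowly and is intended for forward-pass
  inspection and transfer of the architecture, not for reproducing
  headline dataset results.
- Batch statistics make training-mode outputs depend on batch
  composition; evaluation always uses running statistics and is
  batch-size invariant.
- The hierarchical patch-merging of the original windowed-attention
  design is deliberately absent: token grids stay at fixed resolution
  within a branch.
- `window` must divide every token grid a variant produces; the
  configuration validator rejects inconsistent combinations rather than
  padding.
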