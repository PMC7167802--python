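# Methods

This package implements SD-UNet — a depthwise-separable U-Net with weight
standardization (WS) and group normalization (GN) for 2-D biomedical image
segmentation — together with the analytic cost model that motivates it, the
evaluation metrics of the EM-membrane and brain-tumor benchmarks, seeded
synthetic data emulating both regimes, and a CPU training pipeline. This
note records the model, its assumptions, the parameters that matter, and
the design choices made where the design was genuinely open.

## Computational primitives

**Depthwise separable convolution** factorizes a k×k convolution over
M→N channels into a per-channel k×k *depthwise* stage (no cross-channel
mixing, channel multiplier fixed at 1) followed by a 1×1 *pointwise* stage
mixing channels. Per output pixel the multiply count drops from
`k²·M·N` to `k²·M + M·N`; for a square feature map of side `Df` the totals
are `k²·M·N·Df²` versus `k²·M·Df² + M·N·Df²`. The reduction ratio
`k²·N/(k² + N)` is monotone in N and approaches k² — hence ≈8.8× for 3×3
kernels at 512 channels. Bias convention: pointwise and standard
convolutions carry biases, the depthwise stage does not (it is always
immediately followed by the pointwise stage); this is configurable per
layer record but is the default everywhere.

**Weight standardization** reparameterizes a kernel before every forward
pass: `Ŵ = (W − μ)/(σ + ε)` with μ, σ the mean and *population* standard
deviation over all weights feeding one output channel — for a depthwise
kernel, the k² taps of each channel's filter. ε (default 1e-5) is added to
σ itself, not to σ²; the alternative `√(σ² + ε)` formulation exists in the
literature but is not what is implemented here. The optimizer always steps
the raw W; standardization is part of the forward graph, so gradients flow
through μ and σ. WS is applied to the depthwise 3×3 kernels only — not to
the 2×2 decoder convolutions, not to pointwise or standard kernels.

**Group normalization** pools mean and variance over (H, W,
channels-of-one-group) within each example — never across the batch —
then applies a per-channel affine γ·x̂ + β. Default 32 groups; when a
layer is narrower than the group count the layer falls back to G = C
(instance normalization) with a logged warning; widths that are neither
divisible by G nor smaller than G are rejected. Batch normalization is
provided only as a thin standard layer (batch statistics in training,
running buffers with momentum 0.99 at inference) for the ablation grid.

## Architecture

The graph is the widely used 4-pool U-Net encoder–decoder: five encoder
levels of two 3×3 same-padded convolutions (channels
`base_filters`·{1, 2, 4, 8, 16}), 2×2 max-pooling between levels, dropout
(default rate 0.5) at the two deepest levels; a decoder of ×2
nearest-neighbour upsampling + 2×2 convolution + skip concatenation with
the matching encoder level + two 3×3 convolutions; a 3×3 convolution to a
thin prediction stem (2 channels for binary heads, K for K-class heads)
and a 1×1 output convolution with sigmoid (1 channel) or softmax (K
channels). One normalization layer sits at the end of each convolution
block, after the second activation.

SD-UNet keeps the very first convolution standard and replaces every
other convolution with the depthwise separable factorization. This
reconstruction was chosen over a literal reading of the block-by-block
prose description of the architecture because it is the layout whose
accounting reproduces the published sizes exactly: 3,907,973 trainable
parameters (3.9M) for SD-UNet and 31,031,685 (31M) for the all-standard
baseline at a 256×256×1 input with base 64, with kernel-weight FLOPs
(below) of 7.8M and 62.0M. Four max-pools mean input sides must be
divisible by 16; prediction on other sizes reflect-pads and crops back.

The ablation grid is one topology with three switches — separable convs
on/off, GN/BN/none, WS on/off — so the four separable variants share
parameter counts exactly (normalization affines included). The published
26M figure for U-Net + GN is arithmetically inconsistent (GN only adds
parameters to a 31M baseline) and is not reproduced: our `unet_gn` counts
31.0M.

Initialization is seeded He-uniform for kernels (fan-in = receptive
field × input channels; depthwise fan-in = receptive field), zeros for
biases and β, ones for γ. Two builds from equal configs and seeds are
bit-identical.

## Cost accounting

Two FLOP conventions are reported and deliberately kept apart:

* `mult_adds`: the textbook per-output-pixel count (the Df² formulas
  above summed over layers) — what a practitioner usually means.
* `paper_flops`: 2 × (convolution kernel weights, excluding biases and
  normalization affines) — one multiply and one add per kernel weight,
  each kernel counted once. The published size table is internally
  consistent only under this convention (62.04M ≈ 2×31M; 7.8M = 2×3.9M),
  so it is the one the headline numbers and the acceptance script use.

Model size on disk is reported as 4 bytes × parameters (float32,
weights only): 14.9 MB for SD-UNet. The published 372.5 MB / 47 MB
figures for the larger models are consistent with weights plus two
optimizer-moment buffers (3×); the inconsistency between the rows is
documented here rather than reproduced.

## Metrics

Pixel scores from thresholded predictions: accuracy `(TP+TN)/total`,
IOU `TP/(TP+FP+FN)`, Dice `2TP/(2TP+FP+FN)` (algebraically
`2·IOU/(1+IOU)`). Empty-union convention: IOU and Dice are 1 when
prediction and truth are both empty, 0 when exactly one is.

Segment scores compare a predicted label image S to ground truth T
*restricted to T's foreground pixels* (T > 0) via the label contingency
table n_ij:

* **V^Rand** — with pair counts SB = Σ C(n_ij,2), SS = Σ C(s_i,2),
  ST = Σ C(t_j,2): merge score SB/ST, split score SB/SS, combined by the
  equal-weight harmonic mean, which collapses to `2·SB/(SS+ST)`.
* **V^Info** — `2·I(S;T)/(H(S)+H(T))` from the same table with
  0·log 0 = 0; defined as 1 when both labelings are single-segment
  (identical partitions) and 0 when exactly one is.

Predicted-boundary pixels (S = 0) inside T's foreground form their own
segment with id 0. The "maximal after thinning" protocol is approximated
by sweeping a boundary threshold (default 0.05…0.95 step 0.05), labeling
4-connected components of non-boundary pixels at each threshold
(4-connectivity avoids diagonal leakage through 1-px membranes), scoring
each labeling, and taking the maxima; restricting to T-foreground plays
the role of the benchmark's border thinning. This is a faithful
approximation of, not a line-by-line port of, the challenge evaluation
scripts, and leaderboard values computed on hidden test labels are not
reproducible here.

## Losses and optimization

Binary cross-entropy with probabilities clipped at 1e-7; soft Dice
`(2Σpy + s)/(Σp + Σy + s)` with stabilizer s = 1.0 (prevents 0/0 on empty
masks), computed per channel and averaged for one-hot multi-class heads;
the combined objective `w_bce·BCE − w_dice·softDice` with default weights
(1, 1). EM-style binary training uses BCE alone; BRATs-style training
uses the combination. Optimization is Adam (β₁ 0.9, β₂ 0.999, ε 1e-8)
with default learning rates 1e-4 (binary/EM regime) and 1e-5
(multi-class regime), batch size 2 — the micro-batch setting GN exists
for. All computation is float64 numpy on CPU via the in-repo reverse-mode
autodiff engine; every primitive's vector–Jacobian product is validated
against central finite differences in the test suite. Max-pool ties route
gradient to the first maximum.

## Synthetic data

The generators emulate the *statistical structure* the two benchmarks
expose to a segmentation model, not their imaging physics.

EM-like tiles: a seeded point process with minimum-separation rejection
is turned into a nearest-seed tessellation; pixels whose two nearest
seeds are nearly equidistant become 1–3 px membrane walls (width jittered
smoothly across the tile to exercise thinning behaviour). Masks are
binary in-out (interior 1, membrane 0); images are brighter interiors
plus correlated texture and grain, with dark membranes. The default
`cell_density` 0.7 (≈ one cell per 570 px) was calibrated once so the
membrane-pixel fraction stays within [0.05, 0.35] across seeds, and then
frozen. What is *not* emulated: true EM texture (organelles, mitochondria),
slanted membranes of varying contrast, staining artifacts — so passing
tests demonstrate correct mechanics and learnability, not ISBI-grade
difficulty.

BRATs-like slices: four modality-surrogate channels with distinct
contrast responses over a smooth tissue field, and a 4-class label of
nested concentric ellipses — enhancing core inside a non-enhancing ring
inside edema — with exact area ratios 0.2/0.2/0.6 of the tumor ellipse,
so expected class priors are analytic. Tumor area is drawn from
(0.04, 0.12) of the slice, except a configurable 30% of slices carry
small tumors (<2% of pixels) to exercise the small-lesion regime. Not
emulated: bias fields, multi-institution intensity variation, real
lesion morphology.

Preprocessing center-crops (optional), resizes (bilinear image /
nearest-neighbour mask), and standardizes each image per channel to zero
mean and unit variance (constant channels map to zeros). Augmentation
applies seeded horizontal flips, zoom (default 0.9–1.1) and fractional
shifts (default ±10%) jointly to image and mask, nearest-neighbour for
labels, reflection fill; the published augmentation magnitudes are
unstated, so these defaults are configurable.

## Problem sizes and determinism

Desk-scale defaults keep every check on one CPU core: the convergence
run trains a base-8 SD-UNet (69k parameters) on 8 fixed 64×64 EM-like
tiles for 200 Adam steps at learning rate 1e-2 with dropout disabled —
an overfit-sanity setting (the full-scale rates 1e-4/1e-5 are far too
slow for a 200-step window, and regularization is beside the point when
the aim is to fit the training set). Training, generation and prediction
are bit-reproducible given (seed, config, data) on one device: the only
randomness sources are seeded `numpy` generators (initialization, data
shuffling, dropout), and no threading nondeterminism is introduced.

## Known limitations

* The WS benefit reported at full scale does not reproduce at desk
  scale: on the fixed synthetic task the depthwise+GN variant reaches a
  lower median training loss than depthwise+GN+WS over paired seeds
  (e.g., epoch-5 medians 0.034 vs 0.050 at lr 1e-2). A plausible
  mechanism: WS constrains every 3×3 depthwise filter to zero mean,
  removing its local-DC response, while the synthetic task's dominant
  cue is a local intensity offset. The comparison is runnable
  (`examples/compare_ws.py`) and the published claim concerns full-scale
  training, which this package does not attempt.
* `unet_gn`'s published parameter count is not reproduced (see above).
* Full-scale benchmark scores (accuracy/IOU/Dice on the real datasets,
  leaderboard V^Rand/V^Info) require GPU training on external or hidden
  data and are out of scope; the oracle battery and the convergence run
  stand in for them.
* The float64 numpy engine is built for correctness and desk-scale
  sizes, not throughput; full-scale 256×256 training is out of its
  intended envelope.
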