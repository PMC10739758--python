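# Methods

This note records what the package computes, the parameter choices and their
rationale, and the numerical decisions a reader auditing results should know
about.

## Model

The segmenter is a two-branch encoder–decoder over `R × C × 3` images
(`R`, `C` divisible by 32; default 64 × 64) producing per-pixel probabilities
over `c_se = 4` classes (background, unripe, half-ripe, fully ripe).

**Convolutional branch.** Five levels. Each level stacks shape-preservation
blocks (SPBs) and ends in one residual block (RB); the default split is
2+1, 2+1, 2+1, 2+1, 3+1 for 11 SPBs and 5 RBs in total. An SPB keeps spatial
dims and spends exactly 4 convolutions, 4 batch norms and 2 ReLUs
(conv–BN–ReLU–conv–BN main path, conv–BN projection shortcut, sum, ReLU,
trailing conv–BN). An RB spends 3 convolutions, 3 batch norms, 2 ReLUs and one
2×2 stride-2 max pooling (main/shortcut/sum/ReLU, then pool); its pre-pool
activation is the level's skip feature and its pooling argmax indices are kept
for the decoder. Default widths are 16, 32, 64, 128, 256, scaled by a
`width_multiplier` (floor one channel) so small test models preserve the exact
block structure. Total downsampling is 2⁵ = 32.

**Transformer branch.** The image is tiled into `n_p` non-overlapping square
patches of side `P` (default 8). Each flattened patch receives a learned
linear projection to token width `l` (default 128) plus a learned positional
embedding, then passes through a cascade of `t = 3` independent encoders. Each
encoder is pre-norm: contextual multi-head self-attention (CMSA) on the normed
tokens with a residual from the un-normed input, a second layer norm, then a
two-layer ReLU feed-forward whose residual is the *normed* attention sum.
CMSA uses per-head learned Q/K/V maps of shape `(heads, l, l/heads)` and a
bias-free `l × l` merge; attention scores are scaled by `1/√l` — the token
width, not the per-head width. This is a deliberate faithfulness choice (the
source formulation prints `√l`); with default widths it only makes scores
smaller (flatter attention early in training) and is absorbed by the learned
maps.

**Fusion.** The final tokens `p_t` are laid back on their patch grid,
bilinearly resized to the latent convolutional map's spatial dims, projected
to its channel width by a 1×1 convolution, and applied as a multiplicative
gate on the convolutional features (a `concat` mode is also available); a 3×3
convolution yields the fused features. Setting `use_transformer=False` skips
the branch and fusion entirely — the ablation variant shares all remaining
machinery and has strictly fewer parameters (the difference is exactly the
branch + fusion parameter count, which the tests audit).

**Decoder.** Five mirror stages, deepest first: max *unpooling* routed by the
stored argmax indices of the corresponding encoder level, additive skip
connection, then a rescaling unit (conv–BN–ReLU) down to the next level's
width. The mirror pairing keeps skip and unpooled channel widths equal by
construction. A 1×1 classifier and per-pixel softmax finish the model. The
decoder uses 5 unpoolings — one per encoder max-pool — since index-routed
unpooling requires a pooling partner.

## Objective

`L_t = β₁·L_s1 + β₂·L_s2`, with `β₁ + β₂ = 1` (defaults 0.9 / 0.1) and
temperature `τ = 1.5` dividing the logits before the softmax.

- `L_s1` is a per-sample soft dice loss on the temperature-softened
  probabilities: `1 − 2·Σ T·p / Σ(T² + p²)`, sums running jointly over all
  classes (background included) and pixels of the sample, averaged over the
  batch. Value in [0, 1]; robust to the background/foreground imbalance.
- `L_s2` is the temperature-softened cross-entropy, **averaged over samples
  and pixels** (each pixel one classification sample). A per-sample *sum*
  over a 64×64 image would be ~4096× larger than `L_s1` and would swamp the
  convex combination, making the default β weights meaningless; the pixel
  mean keeps the two terms commensurate. The inner sum over classes is exact.
- Log probabilities are floored at 1e-12, so a confidently wrong prediction
  yields a finite loss; the dice denominator carries the same epsilon.
- A zero-weighted component is not evaluated at all (audited by a
  call-counting test).

## Optimization

Adadelta with learning rate 1.00, decay ρ = 0.95, ε = 1e-6, over seeded
mini-batches (default batch 16). The dataset is split 75/25 by a seeded
permutation with `floor(n·fraction)` items to train; a single-item dataset is
its own validation set (the overfitting regime used by the convergence smoke
test). `iterations_per_epoch` defaults to one pass over the training split;
a fixed count oversamples with replacement. Runs are fully seed-deterministic
(split, initialization, batch order, arithmetic). Non-finite losses raise
immediately, naming the epoch, iteration, batch indices and seed. Per-epoch
JSONL log lines are flushed as written; `last.npz` and best-by-validation-mIoU
`best.npz` checkpoints embed the model config as JSON with a SHA-256 hash that
is verified on load.

All tensor math runs on an in-repo reverse-mode autodiff engine over float64
NumPy arrays (`tomaformer.nn`): im2col convolution, reshape-trick 2×2 pooling
with stored argmax, index-routed unpooling, interpolation-matrix bilinear
resize, broadcast-aware matmul, batch/layer norm, max-shifted softmax. Every
primitive's gradient is validated against central finite differences in the
test suite.

## Synthetic scenes: what is and is not emulated

Scenes are discs ("fruit") on a mottled green foliage background. Ripening is
emulated by coloring the bottom `red_fraction` of each disc's rows red; the
class follows the surface-color rule (≥ 0.90 fully ripe, ≥ 0.30 half-ripe,
closed bounds). Fruit are placed by rejection sampling with a ≥ 2-pixel
inter-disc gap, so on occlusion-free scenes the 8-connected-component census
of the mask recovers the generated instances *exactly* — this is what makes
the mask-to-box tests sharp. Elliptical occluder strokes (drawn after the
fruit, relabeling covered pixels to background) and a global lighting gain
emulate leaves and illumination changes. The default instance class mix
(≈ 0.794 : 0.044 : 0.162) mirrors a strongly imbalanced crop census.

Not emulated: perspective, specular highlights, fruit–fruit overlap, texture,
camera noise correlated with depth. The generator is a contract-testing
harness, not a photorealistic simulator; absolute segmentation scores on it do
not transfer to field imagery.

## Metrics

IoU and Dice come from a pooled confusion matrix over the three tomato
classes (background excluded; classes absent from both prediction and truth
are excluded from the means). Detection mAP is mask-derived: each 8-connected
component of a predicted class becomes an axis-aligned box at the min/max
occupied row/column (inclusive bounds), scored by the component's mean
predicted class probability; predictions are sorted by score and greedily
matched to unmatched ground-truth boxes of the same class *and image* at
IoU ≥ 0.5; AP is the area under the all-point-interpolated precision–recall
curve, and mAP the mean over classes that have ground truth. Pixel AUC is
macro one-vs-rest ROC AUC over tomato classes present in the truth.

## The convergence smoke test

The end-to-end learning check trains a width-multiplier-0.25 model for 200
Adadelta steps on a single 64×64 scene and requires final training loss < 0.1
and mIoU > 0.9. The scene is occlusion-free with neutral lighting and 2–3
large fruit. This choice isolates *optimizer and gradient correctness* from
scene difficulty: with occluders and lighting jitter the 200-step budget ends
in the all-background local optimum (loss below 0.1 but mIoU 0), which says
nothing about the implementation. On the pinned regime, seeds 0–3 reach loss
0.009–0.014 and mIoU 0.982–0.994 — a wide margin, so the test is a stable
property, not a tuned threshold.

## Problem sizes

The default 64×64 canvas, width multiplier 1.0 (≈ 11.7 M parameters at full
width; the test models use 0.25 ≈ 0.74 M) and small epoch counts in examples
are package choices sized for CPU execution; the architecture itself is
resolution-agnostic for any dims divisible by 32.

## Limitations

- CPU-only float64 NumPy: throughput is orders of magnitude below a GPU
  framework; the package targets correctness and auditability, not scale.
- Convolutions are stride-1 with same-padding; downsampling happens only via
  pooling, as the architecture prescribes.
- The mask-derived boxes cannot separate touching same-class fruit (one
  component, one box); the generator's non-touching placement sidesteps this
  in tests, but it is a real limitation on natural imagery.
- Batch-norm statistics with batch size 1 rely on per-image spatial
  statistics; the overfit regime works, but very small batches on diverse
  data will be noisy.
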