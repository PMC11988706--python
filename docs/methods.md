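# Methods

This note documents the scientific and numerical choices behind `carunet`:
what the model computes, what the synthetic data does and does not emulate,
how the parameter-budget calibration works, and where the design was
genuinely open.

## Model

The segmentation network is a four-level encoder–decoder on 256×256
grayscale input with a sigmoid head, built from five operators (all NHWC,
same padding so spatial sizes stay powers of two):

**Residual block.** Pre-activation style: BN → 3×3 depthwise-separable
convolution → LeakyReLU, twice; the shortcut is a 1×1 convolution + BN.
Downsampling uses stride 2 in the leading convolutions of the block (both
the depthwise stage and the shortcut), which exactly halves even inputs and
rejects odd ones.  Separable convolutions carry a bias on both stages
(depthwise and pointwise), so a 3×3 block from 8 to 16 channels costs
(72+8) + (128+16) = 224 parameters.

**CBAM.** This implementation follows the printed equations of the source
model rather than the canonical formulation: the channel branch uses *only*
global average pooling (no max-pooling path) into a two-layer bottleneck MLP
with LeakyReLU and a logistic gate, and the spatial branch applies two 7×7
convolutions (channel reduction C → C/8 → 1) directly to the channel-gated
map, not to a concatenated avg/max pair.  Both gates are strictly inside
(0, 1), so attention can only attenuate: |CBAM(U)| ≤ |U| elementwise, which
the tests assert.  With all weights and biases zero both gates are exactly
0.5, giving the analytic limits 0.5·U (single gate) and 0.25·U (both) used
as exact oracle checks.

**ASPP.** Four parallel 3×3 convolutions at dilation rates 1, 6, 12, 18,
each followed by affine batch normalization; branch outputs are summed
elementwise and fused by a 1×1 convolution.  Summation makes the fusion
invariant to branch order, which is asserted by permuting branches.  On the
16×16 bottleneck the rate-18 kernel mostly samples zero padding; that is the
standard behaviour of same-padded atrous convolution and is kept as such.

**Attention gate.** Additive gate σ(ψ ∗ LeakyReLU(θe ∗ enc′ + θd ∗ dec))
with 1×1 projections; the encoder map is brought to the decoder resolution
by a stride-2 1×1 projection, the single-channel gate is bilinearly
upsampled back and multiplies the skip features.  The intermediate channel
count defaults to half the encoder width and is exposed per level
(`gate_channels`) because it is the finest calibration knob available.

**Stem.** Two concurrent paths on the input — (a) 3×3 conv → BN → LeakyReLU
→ 3×3 conv, (b) 1×1 conv → 2×2 max-pool → bilinear upsample — merged by
addition, then BN → LeakyReLU → CBAM.  The exact topology of the published
stem figure is not recoverable from text; this two-path form is the
package's declared canonical choice.

**Ablation ladder.** `unet` (plain double-conv U-Net, max-pool, 2×2
transposed-conv upsampling, ReLU, no BN) → `res_unet` (residual blocks) →
`res_unet_attn` (+ attention gates) → `proposed` (+ stem, CBAM everywhere,
ASPP bridge, bilinear+3×3 decoder upsampling).  The ReLU variant of the
proposed model is the same graph with slope-0 activations and has an
identical parameter count, since activations are parameter-free.  The
proposed decoder upsamples bilinearly followed by a 3×3 convolution rather
than with transposed convolutions; this keeps the budget near 3.24 M and
avoids checkerboard artifacts, while the classical baseline keeps transposed
convolutions.

## Parameter counting and budget calibration

`count_parameters` walks the actual weight arrays; `analytic_param_count`
re-derives the count from the configuration alone with closed forms
(standard conv k²·Cin·Cout + Cout; separable k²·Cin + Cin + Cin·Cout +
Cout; BN 2C trainable + 2C running statistics, the only non-trainable
parameters).  The two are asserted equal on every shipped configuration.

The published budget table pins four totals without per-level widths.  We
treat "millions" as truncation to two decimals and size as
total × 4 B / 2²⁰ rounded to two decimals — the only convention consistent
across all four rows — and intersect the two preimages into integer
windows.  `calibrate_widths` then searches deterministically: a coarse grid
over geometric ladders (base width 8–40, growth ratios 1.8–2.5, attention
reduction and spatial divisor in {4, 8, 16}), followed by beam search over
per-level width adjustments and, for gated architectures, unit changes to
attention-gate intermediate channels (one unit moves the total by
enc+dec+3 parameters, fine enough for the narrowest window, which is only
229 parameters wide).  The shipped defaults are frozen outputs of this
search; the tests re-derive them from the windows.

For `unet`, `res_unet` and `proposed` the calibration also satisfies the
published trainable-parameter column (the total/trainable gap is exactly
2·ΣBN-channels).  For `res_unet_attn` the printed pair (5.86 M total /
5.85 M trainable) would force ΣBN-channels ≤ ~5000 while reaching 5.86 M of
mostly separable-convolution parameters, which is only possible with a
degenerate ≈2300-channel bottleneck; its default is therefore calibrated on
the total window alone and reports 5.84 M trainable.

## Numerical engine

`carunet.autograd` is a reverse-mode tape on numpy arrays.  Convolutions
are computed as sums over kernel taps (k² strided slices, each followed by a
channel matmul), which keeps memory proportional to the activations;
backward scatters gradients tap by tap.  Bilinear 2× upsampling uses
half-pixel-centre alignment (weights ¾/¼, edges clamped) with a hand-written
adjoint.  Batch normalization differentiates through the batch statistics;
running means/variances (momentum 0.9) are used in eval mode.  Python
scalars stay scalars in arithmetic so float32 graphs remain float32.  All
primitives are verified against central finite differences at float64.

Losses: soft Dice 1 − (2ΣPG+ε)/(ΣP+ΣG+ε) with ε = 1e-6 (the empty–empty
case is defined as loss 0); BCE and focal clip probabilities to
[1e-7, 1−1e-7].  The focal modulation uses γ_f = 2.0, α_f = 0.25 (the
standard values; the source does not state them), named `focal_gamma` /
`focal_alpha` to avoid colliding with the compound weights α, β, γ.  At
γ_f = 0, α_f = 1 the focal term reduces exactly to BCE.  Metrics come from
per-image confusion matrices; zero-denominator ratios are 1 when the
corresponding ground-truth set is empty and the prediction agrees, else 0.
Reports average per-image metrics by default; a pooled mode accumulates one
global confusion matrix, since the published tables do not state which
convention they use.

The exact Mann–Whitney p-value enumerates all C(n+m, n) group assignments
when n·m ≤ 64 and counts assignments with |U − nm/2| at least as extreme
(ties contribute ½ to U); larger samples use the normal approximation with
tie correction and continuity correction, which agrees with exact
computation to well under 0.02 at n = m = 20.

## Synthetic phantoms

The generator emulates the bimodal structure a lung-field segmenter must
learn: two bright, vertically elongated, slightly inward-rotated ellipses
(the "lungs", intensity 0.65 by default) on a darker background (0.20),
optional low-amplitude sinusoidal horizontal bands ("ribs", amplitude
0.03), and additive Gaussian noise (σ = 0.05).  Geometry is jittered per
phantom — centre, axis ratio (1.9–2.5), rotation (0.04–0.12 rad), left/right
area share (0.46–0.54) — with the total lung fraction drawn from
[0.15, 0.35], bracketing the typical lung-field area of adult chest
radiographs.  Each ellipse is rasterized by ranking pixels on its quadratic
form and keeping exactly the target count, so the area error is a few
boundary ties rather than O(perimeter).  Every phantom is a pure function
of (seed, index) through a counter-based random stream.

What the phantoms do *not* contain: opacities and consolidations, devices,
clavicle/scapula overlap, cardiac silhouette, exposure variation.  Passing
tests on phantoms therefore demonstrate that the implementation optimizes,
attends and evaluates correctly — not that the model reaches any particular
accuracy on real radiographs, which would require the public CXR datasets
and full-scale training.

## Training protocol and problem sizes

Defaults follow the published regimen: Adam, initial LR 1e-3, batch 32, 50
epochs, Dice loss, LR × 0.1 after 5 epochs without validation improvement
(the patience is not stated in the source; 5 is this package's choice, as is
monitoring the validation loss), best checkpoint by minimum validation
loss.  SGD uses momentum 0.9 and RMSprop framework-typical ρ = 0.9.
Splitting happens before augmentation and only training sources are
augmented, so augmented images never leak across splits; the grid runner
folds the cell index into the seed so each cell trains from scratch
reproducibly.

The package's own verification experiments are deliberately small so they
run on one CPU core: the memorization check trains the quarter-width
proposed model (widths 5, 9, 16, 29, 52) on eight 64×64 phantoms for 200
optimization steps and requires a training-set hard Dice ≥ 0.95 (it reaches
≈1.0); the loss-combination grid runs all seven Dice/BCE/focal combinations
on 32×32 phantoms at toy widths.  These sizes are statements about what the
checks establish — optimization sanity — not about the model's capacity.

## Known limitations

* The published Dice/IoU tables on JSRT/Shenzhen/Montgomery are out of
  scope: they need the real datasets and long GPU training.
* Width calibration pins only the parameter budget; the true per-level
  widths of the published model may differ at equal budget.
* The numpy engine is single-threaded apart from BLAS matmuls; it is meant
  for correctness and desk-scale experiments, not production training.
* The split rule (round-half-up tenths) reproduces the published
  Shenzhen and Montgomery counts exactly but yields 197/25/25 for a
  247-image dataset whose published row sums to 248; the discrepancy is in
  the source table and is left as is.
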