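# Methods

## Model

`mixerseg` implements a five-stage U-shaped encoder–decoder for binary
lesion segmentation of single-channel ultrasound images. Feature tensors
are NHWC; all spatial convolutions are stride-1 with same padding, so at a
power-of-two input every encoder/decoder resolution pairs exactly and the
decoder's centre-crop degenerates to the identity (it is still implemented,
and exercised, for odd intermediate sizes).

Per stage:

* **CBG** (convolved GeLU block): 3 × 3 convolution → batch normalisation →
  GeLU. GeLU uses the exact Gaussian-CDF form `x·Φ(x)`, not the tanh
  approximation.
* **ECM** (enhanced ConvMixer): depthwise 3 × 3 → GeLU → BN → pointwise
  1 × 1 → GeLU → BN → squeeze-and-excitation → residual add of the block
  input. The SE gate pools each channel to its spatial mean, maps
  `c → c/r` (ReLU) and back (sigmoid), and rescales channels; gates are
  strictly inside (0, 1), so the pre-residual output is elementwise bounded
  by its input.
* **CE_MHA** bottleneck: a CBG reduces the deepest encoder output to
  `d_model` channels (the channel reduction that keeps the attention and
  the decoder cheap); the spatial grid is flattened to `h·w` tokens with
  channels as the embedding; four heads of width `d_model/4` apply scaled
  dot-product attention (`softmax(QKᵀ/√d_h)` rows sum to 1); heads are
  concatenated, projected by a 1 × 1 convolution, and added residually to
  the pre-attention features. At the default 128-px input the grid is
  4 × 4 = 16 tokens.
* **ECN** (enhanced ConvNeXt): depthwise 7 × 7 → layer normalisation across
  channels at each position → 1 × 1 back to the input width → residual add
  → 1 × 1 expansion ×4 → GeLU → 1 × 1 contraction → SE.
* **Decoder stage**: 2 × 2 stride-2 transposed convolution to the skip's
  width (+BN+GeLU), centre-crop + concatenation of the skip, ECN refinement
  down to the skip width, and a residual add of the cropped skip.

The head is a 1 × 1 convolution + sigmoid; output probabilities are clipped
to `[1e-7, 1 − 1e-7]` so they are strictly inside (0, 1) even in float32.

### Decoder channel bookkeeping

As written, the ECN preserves its channel count, while the decoder stage
must fuse a concatenation of `2f` channels down to the skip width `f`
before the skip residual can be added. We resolve this by parameterising
the ECN's final 1 × 1 contraction with an `out_channels` argument: decoder
ECNs contract `4·(2f) → f`, standalone ECNs keep `4c → c`. This preserves
the generic "transposed convolution halves the channels" pattern and makes
the skip residual well-typed at every stage. The skip residual is applied
only in the ECN-bearing variants and is controlled by `decoder_residual`
(default on).

### Ablation variants

`model1` uses plain CBG encoder/decoder stages and a convolutional
bottleneck; `model2` adds ECM modules to the encoder; `model3` adds ECN
refinement to the decoder; `hma_net` swaps the convolutional bottleneck for
CE_MHA. The convolutional bottleneck is two 3 × 3 CBG layers at widths
`(w₅ → d_model/2 → d_model)`: narrowing it keeps the decoder identical
across variants and keeps the parameter count strictly increasing along
`model1 < model2 < model3 < hma_net` (attention projections are cheap, so
a full-width two-layer conv bottleneck would out-weigh CE_MHA and break
the ladder).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `input_size` | 128 px | network input side; must divide by 32 (five 2 × 2 poolings) |
| `stage_widths` | (32, 64, 128, 256, 512) | encoder channel widths |
| `width_mult` | 1.0 | global channel multiplier for desk-scale runs |
| `d_model` | `widths[4] / 2` | bottleneck embedding width, divisible by `heads` |
| `heads` | 4 | attention heads |
| `se_reduction` | 8 | SE bottleneck ratio (`c/r ≥ 1` enforced) |
| BN | momentum 0.99, ε = 1e-3 | batch statistics in training mode |
| LN | ε = 1e-6 | per-position channel normalisation |
| optimiser | Adam, lr 1e-3 | no decay or schedule |
| batch / epochs | 8 / 100 | `TrainConfig` defaults |
| Dice ε | 1e-6 | numerator and denominator smoothing |

Weights are Glorot-uniform, drawn from a single `numpy.random.Generator`
seeded by `ModelConfig.seed`; identical config + seed reproduces weights
bit-for-bit and forward passes exactly. Batches of size 0 are rejected;
non-square inputs are accepted when both sides divide by 32.

The layer stack (convolutions, transposed convolution, batch/layer norm,
SE, multi-head attention, pooling, Adam) is implemented in NumPy with
explicit, cached forward/backward passes. Correctness rests on two
independent instruments in the test suite: nested-loop reference
implementations of every primitive, and end-to-end finite-difference
gradient checks on a float64 network.

### Batch-norm statistics at desk scale

With momentum 0.99, a run of a few hundred steps leaves the exponential
running moments far from the statistics the trained weights produce, which
corrupts inference-mode passes. After training (and after the overfit
helper) the running statistics are therefore re-estimated as the arithmetic
mean of batch statistics over the training data — the standard
re-estimation pass used when weights move faster than the EMA tracks. On a
batch whose statistics were just re-estimated, training- and inference-mode
outputs agree exactly.

## Loss, metrics, conventions

The training loss is mean binary cross-entropy over all pixels of all
samples plus the smoothed soft-Dice loss pooled over the batch,
`1 − (2Σyŷ + ε)/(Σy + Σŷ + ε)`; probabilities are clipped before the
logarithm, and the ε in the numerator makes an empty target with an empty
prediction contribute zero.

Thresholded metrics binarise at strict `> 0.5`. Jaccard and Dice of two
empty masks are 1.0 by default (a correctly predicted lesion-free image is
a perfect match); precision/recall with a zero denominator return 1.0 when
the numerator is also zero. Reported metrics are per-image means by
default (column order Jaccard, DSC, recall, accuracy, precision); ROC-AUC
is computed pixelwise over the pooled evaluation set and is undefined —
reported as missing — when the pooled labels are single-class.

## Data pipeline

The reader indexes the public breast-ultrasound folder dialect
(`benign (1).png` / `benign (1)_mask.png`, optional `_mask_1`, `_mask_2`
extra annotations, classes benign/malignant/normal); multiple masks are
unioned, lesion-free images without a mask file get an all-zero mask.
Images are bilinearly resized to the network size and scaled to [0, 1];
masks are nearest-neighbour resized and binarised at 0.5. Splits are
seeded, class-stratified, disjoint and exhaustive (default 20% test).

Augmentation jointly applies one sampled transform to image and mask:
horizontal/vertical flips, shifts up to 10% per axis, zoom up to 20%,
rotation up to 20°, nearest-edge fill; the image is interpolated
bilinearly, the mask nearest-neighbour and re-binarised. Augmentation is
online (fresh transforms per epoch); bounds are validated at construction.

## Synthetic phantoms

The generator emulates the statistics the architecture targets, not
scanner acoustics (no beamforming or k-space simulation):

* smooth tissue texture (Gaussian-filtered noise around base intensity
  0.55) multiplied by unit-mean gamma speckle (variance 0.08);
* 0–2 hypoechoic lesions per frame: ellipses (semi-axes 8–20% of the
  frame) with sinusoidally perturbed radii (up to 25%), optional posterior
  shadow stripes (probability 0.3);
* lesion interiors are set to the attenuated base level
  (`(1 − contrast)·base`, contrast 0.5) rather than attenuated local
  texture — hypoechoic lesions are typically more homogeneous than their
  surroundings, and this makes the interior-darker-than-background margin
  a construction guarantee instead of an expectation (the property test
  allows a 0.8 factor for speckle sampling noise on small lesions);
* masks are the exact union of the analytic lesion supports and are
  reconstructible bit-for-bit from the logged lesion parameters.

Foreground fractions of a few percent reproduce the class imbalance the
combined loss addresses. What passing tests on phantoms do *not* show:
robustness to real speckle statistics, acoustic artefacts beyond the
simple shadow stripe, annotation noise, or scanner/protocol variation.

## Desk-scale study conditions

All training-based tests and the acceptance script run at quarter width
(`width_mult 0.25`) on 64-px phantoms: the 32-phantom task (24 train / 8
held out), Adam lr 1e-3, batch 8, 50 epochs with online augmentation —
sizes chosen so the full four-variant study completes in minutes on one
CPU. The overfit check uses a fixed four-phantom batch and at most 300
steps. At this scale the held-out Dice mean over 8 phantoms is noisy (one
missed lesion costs ≈ 0.125), which is why the ablation-ordering check
carries a 0.05 tolerance; the ordering is a qualitative trend, not a
calibrated effect size.

## Known limitations

* Inputs are limited to sizes divisible by 32; no padding-based handling
  of arbitrary sizes.
* Training runs on CPU via NumPy; wall-clock cost grows quickly with
  width and input size, so full-width 128-px training is out of desk scope.
* Checkpoints store weights, BN statistics and config, but not optimiser
  state; resuming restarts Adam moments.
* Single-class (lesion/background) masks only; no benign-vs-malignant
  distinction in the head.
* An occasional initialisation seed trains to a visibly worse plateau on
  the tiny synthetic task; the study conditions fix seeds for exact
  reproducibility.
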