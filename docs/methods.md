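# Methods

## Problem and model

Brain extraction (skull stripping) is binary semantic segmentation of a
T1-weighted head MRI: label every voxel brain or non-brain.  The difficulty
is concentrated at the brain surface, where dura and skull can be both
spatially adjacent to cortex and nearly identical in intensity.  This
package implements a volumetric encoder–decoder segmentation network whose
output is refined by a fully-connected conditional random field (CRF)
executed as an unrolled, differentiable mean-field recurrent layer, plus
the pre/post-processing pipeline around it and a synthetic-phantom
benchmark that reproduces the adversarial brain/gap/shell structure.

### Network

The backbone is a V-net-style five-level encoder–decoder with an unusual
economy: each level's block runs a stack of 5×5×5 convolutions (each
followed by dropout, channel layer normalisation and ReLU), then sums the
stack's channels back to a **single channel** and adds the block's input
(broadcasting across channels).  All tensors that travel *between* blocks
— downsampled features, skip connections, decoder states — are therefore
one or two channels wide; model capacity lives inside the blocks.
Downsampling is a 2×2×2 stride-2 convolution to one channel (no pooling);
upsampling is the transposed equivalent.  A 1×1×1 convolution produces
two-label logits and a softmax gives the pre-CRF probability map `z`.

The reference configuration is: channel schedule 16·(1, 2, 4, 8, 16),
convolution counts (1, 2, 3, 3, 3) down the encoder and (3, 3, 2, 1) up
the decoder, dropout 0.2 in the first block and 0.5 elsewhere, biases on
every convolution, layer normalisation over channels.  Under this
configuration the base variant has exactly 27,008,316 trainable
parameters.

**Multi-scale inputs.** The raw input volume, average-pooled to each
level's grid, is concatenated to the output of every downsampling
convolution.  Because the block residual *broadcast-adds* a 1-channel
channel-sum onto the (now 2-channel) block input, the raw channel also
propagates into the skip tensors, widening the decoder blocks' inputs to
three channels and the 2³ sampling convolutions by one input channel.
This hookup adds exactly 88,032 parameters.

**CRF recurrent layer.** The network's logits are the negative unary
energies of a fully-connected binary CRF over the 2 mm grid.  Pairwise
potentials use two Gaussian kernels: an appearance kernel over position,
image intensity and learned deep features, and a smoothness kernel over
position alone.  The deep features come from the rear convolution of the
first encoder level (full resolution, 16 channels), passed through a
dedicated 5³ convolution with layer normalisation and ReLU.  The layer's
trainable state is that feature-transform convolution plus the 2×2 label
compatibility matrix (Potts-initialised): 32,052 parameters.  The kernel
weights w1, w2 and bandwidths θα, θβ, θγ, θδ are fixed hyperparameters in
the reference configuration (defaults w1 = w2 = 1, θα = θγ = 3 voxels,
θβ = 0.1 intensity units, θδ = 1 per feature channel); gradients flow
through them, and they can be promoted to trainable parameters by flag.
The three parameter counts above are the calibration anchors of the
reference configuration and are checked exactly in the test suite.

### Mean-field inference

Inference starts from `Q⁰ = softmax(U)` and iterates

    Q'_i = softmax_i( U_i − Σ_{l'} μ(l, l') · (w1 M¹_i(l') + w2 M²_i(l')) )

where `M^m_i(l) = Σ_{j≠i} k^m(f_i, f_j) Q_j(l)` are the kernel-filtered
messages.  Twenty unrolled iterations are the training default (fewer may
be configured for prediction).  Two message-passing paths exist:

* an exact O(N²) reference (pairwise kernel matrix), used as an oracle;
* a truncated-window path that enumerates displacement vectors within a
  radius, precomputes the per-offset kernel maps once per inference, and
  runs each iteration as a windowed filtering with a fused
  forward/backward.  With the radius spanning the grid it is exact; the
  default radius of 2 voxels truncates the Gaussians' tails (at the
  default 3-voxel bandwidths the neglected pair weights are below
  exp(−2) of their peak per axis).  Self-pairs are excluded by filtering
  with the full window (where k(f_i, f_i) = 1) and subtracting Q_i.

**Message normalisation in the recurrent layer.** The raw message
magnitude grows with the kernel support (it is a weighted *sum* over the
neighbourhood), so a few unrolled iterations saturate the update softmax
and zero the gradient — the layer then cannot train.  Inside the network
the messages are therefore divided by each voxel's total kernel mass,
making them weighted neighbourhood averages of Q with O(1) magnitude, as
is standard in CRF-as-RNN implementations.  The standalone
`crf_inference` keeps the textbook unnormalised update by default
(`normalize_messages=False`), which is what the module-level oracles and
the denoising tests exercise.

### Losses and metrics

Training minimises a composite soft-Dice loss

    L = D(y, y_true) − λ · D(z, y),        D(p, t) = 1 − (2 Σ p t + ε) / (Σ p + Σ t + ε)

where `z`/`y` are the pre-/post-CRF foreground maps.  The negative second
term rewards the CRF layer for moving the output away from the base
prediction, preventing the recurrent layer from collapsing into a no-op;
λ defaults to 0.1 (ε = 1e−7).  Plain (non-squared) denominators are used.
Evaluation metrics are the Dice coefficient, Jaccard index and the
symmetric Hausdorff distance (maximum of the two directed distances, not
a percentile variant), computed on the canonical 1 mm grid so voxel units
are millimetres.

### Canonical space and augmentation

All processing happens on a 1 mm isotropic (256, 256, 256) RAS grid with
the world-space centre of the input grid at voxel (128, 128, 128) —
"centre" meaning the voxel `shape // 2`, which makes the transform an
exact identity for already-canonical inputs.  Resampling uses the file's
affine only (no registration): trilinear for images, nearest-neighbour
for masks, zero padding.  Intensities are min–max normalised to [0, 1]
*after* resampling; constant images are rejected.  The network itself
runs at 2 mm (the canonical volume average-pooled by two) and its output
maps are trilinearly upsampled back.

Augmentation draws exactly one transform per image per epoch: intensity
scaling in [0.9, 1.1], intensity shift in [−0.1, 0.1], rotation up to 15°
about a random grid axis, or translation up to 10 mm per axis.  Intensity
augmentations never touch the mask; spatial ones transform image
(trilinear) and mask (nearest) identically.  Augmented values are clipped
back to [0, 1] to preserve the canonical intensity contract.

### Training

Adam at the default learning rate 0.01, one volume per step, 10% of the
data (at least one volume) held out for validation.  Training runs on the
augmented images only, so the per-epoch dataset size never grows.  The
per-epoch history (mean composite training loss, validation Dice loss of
the post-CRF map) is exported as CSV.  A non-finite loss aborts.  All
randomness flows from a single integer seed through numpy Generators, so
runs are exactly reproducible.

### Post-processing

Probability maps are thresholded at 0.5, reduced to the largest
26-connected component (ties broken toward the lowest label index and
logged), and any background region not 6-connected to the grid boundary
is filled.  The 26/6 connectivity pairing prevents diagonal leaks during
cavity detection.  Components are selected before filling.

## Synthetic phantoms

Each phantom is a smoothly deformed ellipsoidal "brain" (default
semi-axes 22 × 18 × 20 mm, mean intensity 0.7, SD 0.05), a dark
cerebrospinal "gap" ring (3 mm, intensity 0.15), and a thin bright
"skull/dura" shell (2 mm, intensity 0.66) on a dim background (0.05),
plus global Gaussian noise (SD 0.03), all clipped to [0, 1] on a 1 mm
64³ grid.  A single low-frequency random displacement field (amplitude
1.5 mm, correlation length one-eighth of the grid) deforms all three
surfaces together, giving sulcus-like boundary complexity while keeping
the truth mask one solid 26-connected component.  Dataset generation
jitters the semi-axes ±10% per sample with per-sample seeds.

The shell is the point: its intensity sits within 0.05 of the brain's, so
no global intensity threshold can reproduce the truth mask (the best
single-threshold Dice stays below 0.95 by construction — asserted in the
tests).  A model must use spatial context to exclude it, which is exactly
the failure mode the CRF layer targets in real T1 data.  What the
phantoms do *not* emulate: anatomical texture (gyri/sulci geometry beyond
smooth deformation), bias fields, partial-volume mixtures at real tissue
interfaces, pathology, or multi-site intensity variation — so passing the
phantom study demonstrates the pipeline's mechanics and the CRF layer's
contribution, not clinical-grade accuracy.

## Study scales

The reference configuration (16 base channels at 128³) is used for the
parameter-count anchors; training studies run a reduced instance of the
same architecture — 4 base channels, 64³ phantoms (network grid 32³), CRF
window radius 1 — sized so a full study fits in minutes on one CPU core.
At this width the reference dropout rates are disproportionate: dropping
half of four channels makes the train-mode and eval-mode statistics of
the channel-sum residuals diverge (training loss keeps falling while
eval-mode output collapses), so the study instance uses dropout 0.1/0.2.
The reference rates 0.2/0.5 remain the defaults of the full-width
configuration.
The end-to-end study trains the full variant on 40 phantoms and evaluates
held-out phantoms with the refined mask; the training-efficiency
comparison trains the full and base variants with identical seeds, data
and epoch budget and compares validation Dice loss at the shared final
epoch.

## Numerical choices and edge cases

* Everything runs in float64; gradient checks compare autodiff against
  central finite differences at 1e−3 relative or better.
* He fan-in initialisation for convolutions; the classifier convolution
  uses a small scale (σ = 0.01) because its input is a channel-sum
  residual of magnitude O(√C) — unit-scale initialisation saturates the
  softmax at the start of training and stalls learning.
* Mean-field updates validate per-voxel normalisation of Q (tolerance
  1e−4 on input, 1e−6 guaranteed on output) and fail loudly on non-finite
  beliefs, naming the offending voxel.
* Empty masks: Dice/Jaccard of two empty masks is defined as 1 with a
  warning; the Hausdorff distance raises; mask refinement raises on an
  empty thresholded mask.
* Component-size ties in refinement keep the lowest-index component.
* The canonical transform is validated as idempotent to 1e−6 and exactly
  invertible (nearest-neighbour) back to the native grid.

## Known limitations

* No GPU path; the engine is single-threaded numpy plus BLAS.  Training
  the full 27 M-parameter reference configuration is out of reach here —
  only scaled instances are trained, and no claim is made about
  real-data accuracy.
* The truncated filtering window makes the "fully-connected" CRF local in
  practice; dense behaviour is available (and tested) only on small
  grids.
* Checkpoints store weights as `.npz` with a JSON sidecar; they are
  configuration-locked (a checkpoint only loads into the configuration
  that produced it).
* The phantom benchmark is deliberately easy relative to real T1 data;
  see the phantom section for what it does not model.
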