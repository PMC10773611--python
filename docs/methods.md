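# Methods

`tribrats` reimplements a tri-planar ("2.5D") whole-tumor segmentation
pipeline for multimodal brain MRI: quality screening of the four input
modalities, intensity normalization, slicing of the 3D volumes into the
three anatomical planes, 2D encoder–decoder segmentation networks
trained with the generalized Dice loss, and voxelwise majority-vote
fusion of the per-plane predictions. This note records the models, the
conventions the implementation fixes where the problem statement leaves
them open, and the limits of what the synthetic phantom study can show.

## Data model

A case is four co-registered modality volumes — FLAIR, T1ce, T1, T2 —
plus a binary whole-tumor mask on one voxel grid. Axis 0 is the
sagittal normal, axis 1 the coronal normal, axis 2 the axial normal.
Multi-class lesion labels are collapsed to whole tumor (any nonzero
label → 1) on read, because the networks end in a single sigmoid unit:
the task is binary. BraTS-style data are assumed skull-stripped with an
exactly-zero background, which is why `intensity > 0` doubles as a
brain mask throughout the preprocessing stage.

## Defect screening (Dixon's Q)

Truncated acquisitions leave one modality covering visibly less anatomy
than its three siblings. Per modality we binarize each axial slice at
intensity > 0, keep the largest 8-connected component, trace its outer
boundary (Moore neighbour tracing) and take the shoelace area of the
polygon through the boundary-pixel centres — the classical contour-area
convention, which yields half-integer areas for diagonal boundaries and
gives (k−1)² for a filled k×k square. The per-case representative area
is the mean over axial slices (the aggregation is a package convention;
a single-slice variant would behave the same on truncations that affect
every slice).

Dixon's Q for a low outlier among the four areas is

    Q = (x(2) − x(1)) / (x(n) − x(1)),   x(1) ≤ … ≤ x(n), n = 4,

compared against the n = 4 critical-value row
{α: 0.001→0.964, 0.002→0.949, 0.005→0.921, 0.01→0.889, 0.02→0.847,
0.05→0.766, 0.1→0.679, 0.2→0.561}. The screening level defaults to
α = 0.001. Only the low extreme is tested — truncation can only shrink
an area. A zero range is defined as Q = 0 (no outlier): four identical
areas are the healthy case. Q is scale- and shift-invariant and lies in
[0, 1]; both are property-tested.

## Intensity normalization

**Bias field.** Scanner coil inhomogeneity multiplies MRI intensities
by a smooth, strictly positive field. The corrector fits a total-degree-2
polynomial in normalized coordinates to log-intensities over the
foreground by least squares, exponentiates the mean-removed fit into a
field with mean 1 over the foreground, divides it out, and rescales so
the foreground mean is preserved. Voxels outside the 5th–95th
percentile of log-intensity are excluded from the fit so lesions (the
intensity tails) do not steer the field estimate. This is a
deliberately simple, deterministic member of the same multiplicative
smooth-field model family as the N4 algorithm; the `config` hook allows
substituting a full N4 backend. It is validated by recovery: for
injected exponential-quadratic fields of strength 0.3 the estimated
field correlates with the injected one at r ≥ 0.95 over the foreground
across seeds.

**Z-score.** Each modality volume is standardized as z′ = (z − μ)/δ
with μ and δ (population standard deviation) computed over foreground
voxels only; background stays 0 and a constant foreground maps to 0
(δ-guard). The foreground mask is "nonzero voxels": identical to
`> 0` on raw MRI, and it makes the operation exactly idempotent, which
the whole-volume `> 0` convention would not be once negative z-scores
exist.

**Resizing.** In-plane bilinear (nearest-neighbour for masks), slice
count unchanged — e.g. 240 × 240 × 155 → 128 × 128 × 155 at full scale.

## Tri-planar slicing and channel combos

Each volume is sliced along one of the three anatomical axes; non-square
slices are resized per slice to the network's square input, and
predicted probability maps are resized back before restacking, so the
3D round trip is exact when no resize is involved. Empty slices are
kept — index bookkeeping stays trivial, and the class imbalance is
handled by the loss and the sampler, not the geometry.

The EfficientUNet path evaluates four ordered three-channel modality
combinations per plane — (FLAIR, T1ce, T1), (FLAIR, T1ce, T2),
(T2, T1ce, T1), (FLAIR, T1, T2) — and selects per plane the combo with
minimum training loss (ties: higher DSC, then enumeration order).
Max-DSC selection is available but not the default: minimum loss is
the rule consistent with the published per-plane choices. The plain
U-Net consumes the full four-modality stack by default (configurable).

## Networks

Both networks are fully convolutional 2D encoder–decoders ending in a
1 × 1 convolution and a sigmoid.

**U-Net.** Five levels of two 3 × 3 conv + batch-norm + ReLU, widths
doubling from `base_filters` = 32 (32→512), 2 × 2 max-pool between
levels; the decoder mirrors with nearest-neighbour 2× upsampling, skip
concatenation, and two convs per block. Nearest-up + conv replaces
transposed convolution to avoid checkerboard artifacts. The reference
configuration (depth 5, base 32, four input channels) has 7,849,889
parameters, verified against closed-form layer arithmetic in the tests.

**EfficientUNet.** The encoder is an EfficientNetV2-S: stride-2 stem
(24 ch), Fused-MBConv stages (expansion 1, 4, 4; channels 24, 48, 64;
repeats 2, 4, 4) and MBConv stages with squeeze-excitation ratio 0.25
on the block input width (expansion 4, 6, 6; channels 128, 160, 256;
repeats 6, 9, 15), SiLU activations, residual shortcuts where stride
and width permit. The classification head (1 × 1 conv / pooling / FC)
has no role in dense prediction and is dropped; instead the encoder
exposes feature taps at each resolution halving (after stages 1, 2, 3,
5, 6). The decoder is five conventional blocks (2× upsample, concat
tap, two 3 × 3 conv-BN-ReLU); its widths mirror the tap widths, the
final full-resolution block keeping the last tap's width — a recorded
convention, since only the encoder table is published. Channel widths
scale by `width_mult`, rounded to the nearest multiple of 8 (half up,
minimum 8), so a width-0.25 instance (1,425,103 parameters) trains on
one CPU in minutes.

## Loss and metrics

The generalized Dice loss with the per-label weight w = 1/(Σg):

    GDL = 1 − (2 Σ_l w_l Σ g p + ε) / (Σ_l w_l Σ (g + p) + ε),  ε = 1e-6,

sums pooled over the batch. One foreground label is used (binary task);
the implementation supports L > 1 via a channel axis. The ε placement
makes the empty-vs-empty limit 0 and perfect overlap 0. For hard
predictions and a single label, DSC = 1 − GDL to ε accuracy — an
identity the tests exploit as a cross-check between the evaluation
metrics and the differentiable training loss.

Pixel accuracy (TP+TN)/total and DSC = 2TP/(2TP+FP+FN) are computed
from voxelwise confusion counts; empty-vs-empty DSC is defined as 1.
Reports are (loss, accuracy, DSC) triples, per case and aggregated.

## Training

Adam at learning rate 1e-4, sigmoid output, generalized Dice loss, 30
epochs, batch size 8 — the full-scale defaults (`TrainConfig`). Splits
are case-level, seeded, with floor-rule validation/test sizes: 331
cases at 7 : 1.5 : 1.5 give 233/49/49. The training stream uses
class-balanced slice sampling by default: every tumor-containing slice
plus an equal number of tumor-free slices per case (seeded draw).
Tumor voxels are a percent-scale minority, and without balancing most
gradient steps carry no foreground signal.

**Desk-scale study.** The phantom experiment the test suite runs
(`pipeline.desk_scale_experiment`) trains a width-0.25 EfficientUNet on
64 × 64 inputs for 5 epochs on 12 phantom cases (4 held out), one model
per plane, then fuses tri-planarly. Because this shrinks the step
budget by roughly 60× relative to the full-scale schedule, the Adam
step size is scaled up one decade to 1e-3 for this recipe; at 1e-4 the
optimizer cannot traverse the distance from random initialization to a
useful segmenter within 5 epochs (measured: held-out DSC ≈ 0.36 versus
≈ 0.95 after scaling). The full-scale default remains 1e-4.

## Ensembling

Per-plane probabilities are reassembled to 3D, binarized at 0.5 (with
the ≥ convention), and fused voxelwise by the 2-of-3 majority rule —
hard-mask voting, as "majority voting" implies; probability averaging
exists as an off-by-default mode. The fused mask always lies between
the AND and the OR of its inputs.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes:
an ellipsoidal brain (semi-axes ≈ 0.44 of the grid per axis) of
constant mean tissue intensity on an exactly-zero background; 1–2
spherical tumors (radius 4–9 voxels at the default 64 × 64 × 48 grid)
with the clinical contrast pattern — hyperintense on FLAIR/T2 (≈ +80%
over brain), hypointense on T1 (≈ −40%), and on T1ce a bright rim
(outer 30% shell, ≈ +80%) around a mildly hypointense core; additive
Gaussian noise (σ = 4 intensity units against brain ≈ 100–120) inside
the brain only. Corruption operators: a multiplicative
exponential-quadratic bias field (mean 1 over the brain) and a
truncation defect that zeroes a contiguous band (default 40% of the
first in-plane axis) of one modality, sized so the Q-test fires at
α = 0.001. Everything is a pure function of its seed.

What the phantoms do **not** model: real lesion morphology and texture,
partial-volume effects, Rician noise, k-space artifacts, registration
error, or anatomy beyond a homogeneous ellipsoid. Passing the phantom
study shows the pipeline's plumbing, losses, and fusion logic behave as
specified and that the networks can learn a strongly-contrasted lesion;
it does not certify performance on clinical BraTS data, which requires
the external dataset and GPU-scale training.

## Numerical choices

* All network arithmetic is float32; convolutions are shift-and-add
  (one BLAS matmul per kernel offset), chosen over im2col for CPU speed
  at small channel counts. Gradients are validated against central
  finite differences.
* Batch-norm: momentum 0.9, ε = 1e-5; inference uses running statistics.
* Sigmoid/SiLU use the numerically stable two-branch form (no overflow).
* Probability threshold 0.5 with ties counted as foreground.
* Dixon's Q with zero range → 0; z-score with zero spread → 0;
  empty-vs-empty DSC → 1; these degenerate-input rules are tested.
* Phantom tumor placement rejects positions whose sphere would cross
  the brain surface (200 attempts, then a placement error).

## Known limitations

* The bias corrector is a global polynomial fit: adequate for smooth
  low-order fields, not for high-frequency inhomogeneity.
* The contour-area convention returns 0 for single-pixel and
  one-pixel-wide components (a degenerate polygon has no area).
* Training is single-threaded CPU; the full-scale 128 × 128 × 155
  configuration is expressible but not practical without hardware
  acceleration.
* The EfficientUNet decoder widths and the U-Net filter plan are
  inferred conventions; parameter totals therefore match published
  reference figures only approximately (U-Net within 1%).
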