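# Methods

## Problem and model

Cervical (and other pelvic) tumors are delineated on multiparametric MRI:
anatomical T2-weighted (t2w) images, high-b diffusion-weighted images
(b1000), and apparent-diffusion-coefficient (ADC) maps. The DWI channels
are acquired with echo-planar imaging and are geometrically distorted
along the phase-encode axis, so they are *misaligned* with the t2w image
on which ground-truth contours are drawn. Conventional multi-channel
segmentation networks stack the channels and implicitly assume voxel
correspondence; this package implements an architecture family that
relaxes that assumption.

The trunk is a 3D residual U-Net: four stride-2 downsampling levels with
filters (32, 64, 128, 256) and a 512-channel bottleneck, each level made
of two residual blocks (3D conv → instance norm → PReLU, twice, plus an
additive identity path projected by a 1×1×1 conv when shapes change;
downsampling happens in the first conv of a level); the decoder mirrors
the encoder with kernel-2/stride-2 transposed convolutions and skip
concatenation. The output is a single-channel sigmoid (binary task).

The multi-head variants replace the *first encoder level* with parallel
encoding heads:

| variant      | heads (channels @ dilation)                    | sharing      | fusion                 |
|--------------|------------------------------------------------|--------------|------------------------|
| multihead_1  | t2w@1, {t2w,b1000,adc}@2, {t2w,b1000,adc}@4    | shared       | sum                    |
| multihead_2  | t2w@1, {b1000,adc}@2, {b1000,adc}@4            | shared       | sum                    |
| multihead_3  | t2w@1, {b1000,adc}@2, {b1000,adc}@4            | independent  | concat → 1×1×1 → sum   |

Dilated convolutions pad by their dilation rate, so all heads emit equal
spatial shapes and summation fusion is well-defined. "Shared" means the
two dilated heads literally reuse one set of convolution kernels (the
same tensors applied at dilation 2 and 4, identity-path projection
included), which keeps the parameter count essentially flat relative to
the baseline; this is our reading of head weight sharing — the
alternative (independent kernels even in variants 1/2) is available via
``ModelConfig(shared_head_kernels=False)``. In ``multihead_3`` the two
dilated head outputs (2×32 ch) are concatenated, projected to 32 channels
by a 1×1×1 convolution, and summed with the t2w head.

Other architectural choices the source material leaves open, fixed here:
kernel 3×3×3 everywhere (anisotropy is handled by the patch shape, not
the kernels); transposed-conv kernel 2, stride 2; PReLU slope initialized
at 0.25, learned per channel; Kaiming fan-in initialization, seeded.

## Numerical stack

The networks are built on an in-package reverse-mode autodiff engine over
NumPy arrays (`mhseg.nn`): conv3d is an im2col strided-view gather plus a
BLAS `tensordot`, with the input-gradient scatter looping over the 27
kernel taps; transposed conv with kernel = stride is a reshape-einsum;
instance norm and PReLU use the standard closed-form backward passes. All
primitives are verified against central finite differences to ~1e-8 in
float64; training runs in float32. The engine retains gradients on
intermediate tensors after `backward()`, which is what Grad-CAM needs.

## ADC fitting

Mono-exponential decay S_bi = S_b0·exp(−b_i·D). Two estimators:
two-point, D = −(1/b)·ln(S_b/S_0); and the closed-form log-linear
least-squares slope over multiple b-values (customarily b200/b600/b1000,
excluding b=0 — include it by simply putting it in the series). D is in
mm²/s. Voxels with non-positive signal are marked invalid and filled
(default 0) rather than clamped to an epsilon, which would fabricate
extreme D values; noise-induced negative D is retained unless
`clip_negative` is set, preserving the estimator as defined.

## Phantoms

The models are verified on synthetic phantoms because the patient data
such models are trained on cannot be shared. Each phantom has: a
hyperintense tumor ellipsoid on t2w (contrast 0.4 over a 0.4 background
with low-frequency seeded texture, plus a few non-tumor ellipsoids at
0.15 contrast as clutter); a diffusion map with d_tumor = 0.9e-3 mm²/s
inside the tumor and d_background = 1.8e-3 mm²/s outside (impeded
diffusion in cellular tumor, values typical of pelvic soft tissue); b=0
signal 0.5 background / 0.8 tumor; additive Gaussian noise on magnitude
images clipped at 0 (a deliberate simplification of Rician statistics —
adequate for pipeline testing, biased at very low SNR); and a smooth
displacement field along the phase-encode axis (y) applied only to
DWI-derived quantities, built from 2–4 seeded Gaussian bumps rescaled so
the peak displacement equals `distortion_magnitude_mm`.

Synthesis order matters: the diffusion map and b=0 signal are warped
first and the b_i signals computed from the warped quantities, so
−ln(S_bi/S_b0)/b_i equals the (warped) diffusion map to 1e-10 even on
distorted phantoms. The tumor mask stays on the undistorted t2w geometry:
with a supra-voxel distortion the DWI tumor support and the mask have
DSC < 1, i.e. the misalignment the architecture targets is really there.

What the phantoms do **not** emulate: pelvic anatomy, Rician noise,
k-space/EPI physics, multi-scanner intensity variation, partial-volume
effects, or observer variability in contours. Passing tests therefore
demonstrate that the pipeline is mechanically and numerically correct and
that the architecture behaves as designed — not that it reaches clinical
accuracy on real data.

## Preprocessing and training

Fixed pipeline order: resample → normalize → (training only)
patch-sample → augment. Resampling is linear for t2w/b-value images and
nearest-neighbor for ADC (quantitative) and masks (categorical); the
reference spacing for patient-scale data is 0.6×0.6 mm in-plane and 4 mm
slices. Normalization is per-channel zero-mean/unit-variance over the
whole volume (the plainest reading of per-channel normalization; constant
volumes are rejected). Patches (default 256×256×16 voxels) are drawn
uniformly, rejection-sampled (cap 100, then centered on the tumor
centroid) so at least one z-slice contains tumor; volumes smaller than
the patch are symmetrically zero-padded. Augmentation: per-channel
intensity shift (±0.1 of the patch std), global scale in [0.9, 1.1], and
an integer in-plane crop-and-pad jitter of up to 8 voxels applied to
channels and mask alike; the mask never receives intensity transforms.

Training: Adam (lr0 = 1e-4, weight decay 1e-5 as L2-in-gradient), cosine
annealing stepped per epoch, soft Dice loss by default (ε = 1e-5), with
Dice+cross-entropy (1:1) and Tversky (α, β = 0.3, 0.7) as alternatives.
An "epoch" is an iteration budget (`epoch_length`, default 250) because
stochastic patch sampling has no natural data pass; after each epoch the
model is validated by sliding-window inference on whole volumes (mean
DSC) and the best weights are kept (first strict maximum). Batch size
defaults to 2 (desk preset 1). All randomness flows from explicit seeds;
identically seeded runs produce identical loss curves.

## Inference and metrics

Sliding-window inference tiles the reflect-padded volume with 75% overlap
(stride = patch/4), averages per-window sigmoid probabilities uniformly
(Gaussian weighting was considered and rejected: uniform means the
constant-input invariant is exactly testable), crops to the input shape,
and thresholds at 0.5. Metrics: DSC; HD95 and MSD over the *pooled
bidirectional* surface-distance multiset (one of several HD95 conventions
— stated so numbers are comparable); signed relative volume difference
100·(|P|−|R|)/|R| (negative = underestimation). Surfaces are
6-connectivity border voxels and distances are voxel-center distances in
mm. Degenerate pairs: both masks empty → DSC 1, distances 0, flagged;
empty reference → flagged undefined. Cohort summaries report medians with
seeded percentile-bootstrap 95% CIs (1000 resamples).

## Interpretation

Channel dropout zeroes one normalized channel at a time at test time
(zero = channel mean in original units) and re-measures all four metrics;
the table has one row per channel plus the no-dropout baseline and is
bit-reproducible. Grad-CAM: target scalar = sum of foreground logits over
predicted-positive voxels (ground-truth-mask targeting available via
``target=``); weights = spatial mean of the target's gradients w.r.t. the
chosen layer's feature maps (default: the last decoder residual block
before the output conv); map = rectified weighted sum, trilinearly
upsampled, min-max normalized per volume to [0, 1]. Inputs whose spatial
dims are not multiples of 16 are reflect-padded for the forward pass and
the map is cropped back.

## Desk-scale presets and determinism

The reference training recipe (100k iterations, 256×256×16 patches,
full-width network) is far beyond a single CPU, so tests and the
acceptance script use desk presets chosen once: phantoms of 24×24×16
voxels at 1.5×1.5×3.0 mm, 16×16×16 patches, width multiplier 0.25
(filters 8/16/32/64, bottleneck 128), 500 iterations for the single-
phantom overfit check and 300 iterations per model for the 20-phantom
misalignment comparison (15 train / 3 val / 2 test by the usual
157:25:25 proportions). At this scale the overfit check reliably reaches
whole-volume DSC > 0.8 and the end-to-end comparison runs to completion;
the *relative ranking* of the architectures at desk scale is within
run-to-run noise and is reported, not asserted.

## Known limitations

- Gaussian (not Rician) noise on magnitudes; no scanner ADC noise-floor
  handling — no attempt to match vendor ADC maps.
- The displacement field is a free parameter, not calibrated to any
  cohort's actual distortion.
- The receptive-field probe (`head_gradient_footprint`) measures the
  convolution path only; instance-norm statistics couple all voxels
  globally and would mask the local footprint.
- Single foreground class; no test-time augmentation, ensembling, or
  connected-component post-processing.
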