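# Methods

## Problem and pipeline

A 3-D brain MR volume can be reconstructed from two-dimensional operations
alone.  Given a half-resolution volume (e.g. 128 x 128 x 75 voxels for a
native 256 x 256 x 150 acquisition), the pipeline is:

1. **Tri-planar slicing.** The half volume is sliced along the sagittal,
   coronal and axial planes.  Slice *i* of the half volume corresponds to
   slice 2*i* of the target grid — the half volume realizes a "keep one,
   skip one" decimation (interval of 1 slice) starting at index 0, so even
   source indices survive.
2. **First super-resolution pass.** Every slice of every plane is
   super-resolved x2 by the stage-1 generator (an RFB-ESRGAN: a
   residual-in-residual dense trunk followed by residual receptive-field
   dense blocks and a sub-pixel upsampler).
3. **Rebuild with missing voxels.** The super-resolved slices are written
   back at their (even) source indices.  A voxel is covered by the sagittal
   stack iff its x index is even, the coronal stack iff y is even, the axial
   stack iff z is even; a voxel with all-odd coordinates is written by no
   plane.  On even-dimension grids exactly 1/8 of the voxels are missing.
   The rebuild tracks an explicit per-voxel contribution count and missing
   mask; the sentinel intensity 0 is never used for detection because 0 is a
   legal intensity.
4. **Second restoration pass.** Every slice of every plane of the rebuilt
   volume is passed through the stage-2 generator (nESRGAN, same-size), and
   the three full output stacks are merged.  No voxels remain missing.

The classical alternative for step 4 — iteratively replacing each missing
voxel by the mean of its known face-adjacent neighbors — is provided as the
`interpolation_repair` baseline (volumetric 6-connected by default, with a
slice-wise 4-connected mode).

## Networks

Both generators are 1-channel (grayscale) and follow the ESRGAN lineage:
RRDB units contain 3 dense blocks of 5 convolutions (growth = base_channels/2
by default), residual-scaled by 0.2; LeakyReLU slope 0.2 throughout; all
convolutions are initialized at 0.1 x Kaiming scale and every block-final /
network-final convolution at exactly zero.

**Global skips and the interpolation reduction.** The stage-1 generator adds
its learned residual to a Keys bicubic (a = -0.5) x2 upscaling of the input;
the stage-2 generator adds its residual to the input itself.  Because the
final convolution is zero-initialized, a freshly built stage-1 network *is*
bicubic upscaling and a freshly built stage-2 network *is* the identity.
Training therefore starts from the classical interpolation baseline and can
only be changed by gradient evidence.

**Receptive-field blocks.** Each RFB runs four parallel branches — 1x1;
1x1-3x3; 1x1-3x3 (dilation 3); 1x1-(1x3)-(3x1)-3x3 (dilation 5) — concatenated
and fused by a 1x1 convolution, residual-scaled by 0.2.  An RRFDB chains
three RFB units inside an outer 0.2-scaled residual.

**Noise injection (stage 2).** After each dense block's fused output the
stage-2 generator adds Gaussian noise scaled by a learned per-channel
strength, zero-initialized so the injection is an exact no-op at init.  In
training mode fresh noise is drawn from a per-module seeded stream; in eval
mode the noise is frozen (regenerated from the module seed), so inference is
deterministic and repeatable.

**Sampling without deconvolution.** The stage-2 network downsamples at its
entry (linear resampling to ceil(H/2) x ceil(W/2) — odd sizes are restored
exactly by resampling back to H x W, which subsumes the pad-then-crop
handling in one mechanism) and upsamples by interpolation followed by
convolution.  No transposed convolution exists anywhere in the backend, so
checkerboard artifacts are excluded structurally, not just empirically.

**Discriminator.** A VGG-style stack over widths (64, 128, 256, 512), each
width with a stride-1 then a stride-2 convolution, batch norm except on the
first layer, ending in two fully connected layers that produce one raw
(pre-sigmoid) logit per image.

## Losses

The composite generator objective is

    L_G = L_percep + lambda * L_adv + eta * L1

with defaults lambda = 5e-3 and eta = 1e-2 (the ESRGAN-lineage convention;
the balancing coefficients have no published values for this pipeline and
are freely configurable).  L1 is the mean absolute pixel error.  L_percep is
an L1 distance in the feature space of a pluggable extractor; pretrained
VGG-19 weights are deliberately not shipped, so the package provides an
identity extractor (L_percep then equals the pixel L1) and a seam for a
user-supplied extractor.  The adversarial terms are the relativistic-average
GAN forms: with C(.) the raw discriminator output,

    D_ra(x_r) = sigmoid(C(x_r) - E[C(x_f)]),
    D_ra(x_f) = sigmoid(C(x_f) - E[C(x_r)]),
    L_D    = -E[log D_ra(x_r)] - E[log(1 - D_ra(x_f))],
    L_G^Ra = -E[log(1 - D_ra(x_r))] - E[log D_ra(x_f)].

Expectations are batch means; log arguments are clamped to [1e-8, 1].  On
equal real/fake logits both losses equal 2 log 2; both are invariant to
adding a constant to all logits.  Stage-1 pretraining uses the pixel L1
alone; stage-2 fine-tuning starts the generator from the stage-1 checkpoint
against a freshly initialized discriminator, alternating D and G steps
(Adam, lr 1e-4 stage 1 / 1e-5 stage 2 at full scale — the optimizer is a
free choice, no published setting exists for it).

## Intensity convention and metrics

Volumes are min-max normalized to [0, 1] per volume on read; the raw range
is kept in the NIfTI `descrip` header so write -> read round trips are exact
and intensities can be denormalized.  PSNR is 10 log10(MAX_I^2 / MSE) with
MAX_I = 1.0 under this convention (configurable; absolute dB values are only
comparable across codebases when the convention matches).  SSIM uses the
standard stabilizers c1 = (0.01 L)^2, c2 = (0.03 L)^2 and a 7x7 uniform
window over fully interior positions (Gaussian 11x11 sigma 1.5 selectable).
Identical slices score PSNR = +inf; such slices are flagged and excluded
from plane means rather than averaged.  Volume evaluation reports
mean +/- std over slices, per plane.  LPIPS is exposed only as an adapter
for a user-supplied scorer: absent or failing scorers skip the metric with a
notice, never an error.

## Synthetic phantoms

Real T1 volumes are large and not redistributable, so all tests run on
synthetic phantoms: a near-zero background, 8-12 random Gaussian ellipsoids
(the smooth "anatomy"), an additive band-limited texture field (difference
of Gaussian-smoothed white noise at texture_scale 3.0 voxels, amplitude
0.08, confined to the foreground — roughly 70% of its energy lies in the
0.10-0.25 cycles/voxel band that x2 bicubic degradation attenuates but a x2
network can restore), and additive Gaussian acquisition noise (sigma 0.01 on
the [0, 1] scale), clipped to [0, 1].  Generation is bit-deterministic under
the seed.  The phantoms deliberately do **not** model MRI physics (bias
fields, k-space sampling, Rician noise, anatomy): passing tests demonstrate
that the geometry, losses, optimization and reconstruction machinery are
correct, not that the trained networks transfer to clinical data.

The small-test shape default 64 x 64 x 38 mirrors the parity pattern of the
native grid (150 halves to the odd 75), so even/odd edge cases are always
exercised.

## Degradation model

Low-resolution inputs are produced by bicubic downscaling implemented from
the Keys (a = -0.5) cubic convolution kernel with half-pixel-center mapping
and edge clamping; each output dimension is ceil(dim/scale).  Patch pairs
(16x16 LR / 32x32 HR, non-overlapping stride by default) can degrade either
the HR crop itself (exact border alignment) or the whole slice before
cropping (the operator whole-slice inference actually inverts); the
scaled-down experiments use slice-level degradation for that reason.
Volume-level x2 downscaling uses order-3 spline interpolation.

## Scaled-down demonstration conditions

Full-scale training (16 RRDBs, 8 RRFDBs, 64 channels, GPU-scale schedules)
is out of desk range, so the package's standard demonstration config is: 10
phantoms of 48 x 48 x 36 voxels split 7:3, generator with 2 RRDBs, 1 RRFDB,
12 channels (growth 6), batch 16, 200 Adam steps.  The demo learning rate
was calibrated by a sweep over {1, 2, 3, 5}e-3 scored only on training-set
L1 descent and stability over the 200-step schedule (held-out metrics were
not consulted); the sweep and its result are reproducible from
`trisr.experiments`.  Under these conditions short training starts exactly
at the bicubic baseline (the zero-initialized network) and is compared
against bicubic upscaling on held-out phantom slices.

Two properties of these conditions are worth knowing when reading results.
First, because targets carry clipped Gaussian noise, the background noise
distribution is asymmetric: L1 training pulls predictions toward the median
(darker than the mean), which can trade a little PSNR for L1 early in
training before deconvolution gains dominate.  Second, at desk scale the
margin over bicubic is small (tenths of a dB at ~1000 steps); the
demonstration shows the optimization learns in the right direction, not the
paper-scale quality gap.

## Numerical backend

The networks, losses and training loop run on a small reverse-mode
autodiff library over numpy float64 arrays (`trisr.nn`): convolution with
stride/dilation via im2col + GEMM, batch norm, pixel shuffle, nearest and
separable linear/cubic resampling (backward = exact adjoint), dense layers,
and Adam.  float64 keeps analytic gradients within 1e-4 of central finite
differences, which the test suite checks directly.  Checkpoints are `.npz`
archives with an embedded JSON architecture header, so a generator can be
rebuilt from its checkpoint alone.

## Known limitations

- Phantoms are not brains; no claim of clinical image quality transfer.
- The perceptual loss is only exercised through the identity extractor
  unless the user plugs in pretrained VGG weights; LPIPS likewise.
- The brightness differences between adjacent rebuilt slices seen on real
  data have no published quantitative correction and none is implemented.
- Overlapping plane predictions are averaged (order-independent); a
  priority merge (axial > coronal > sagittal) is available but the choice
  between them on real data is unvalidated.
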