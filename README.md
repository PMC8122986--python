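# trisr — two-stage 2D-GAN super-resolution reconstruction of 3D brain MRI

Low-field MR scanners trade resolution for scan time.  Instead of
super-resolving a brain volume with an expensive 3-D convolutional network,
`trisr` reconstructs it with two *2-D* passes over the three anatomical
planes:

1. A half-resolution volume (e.g. 128 × 128 × 75 for a native
   256 × 256 × 150 grid) is sliced sagittally, coronally and axially, and
   every slice is super-resolved ×2 by an **RFB-ESRGAN** generator — a
   residual-in-residual dense trunk followed by residual receptive-field
   dense blocks (multi-branch small/dilated kernels) and a sub-pixel
   upsampler.
2. The super-resolved slices are rebuilt into a volume at target resolution.
   Each plane only covers the even indices along its axis, so voxels whose
   three coordinates are all odd are written by no plane: exactly **1/8 of
   the voxels are missing** on even-dimension grids.  A second, same-size
   restoration network (**nESRGAN** — ESRGAN with learned-strength Gaussian
   noise injection and interpolation-based sampling instead of
   deconvolution) traverses all slices of the rebuilt volume and repairs it.

Training follows the two-stage GAN recipe: L1-only pretraining, then
fine-tuning with

    L_G = L_percep + λ·L_adv + η·L1,

where the adversarial terms are the relativistic-average GAN losses
(sigmoid of logit differences against the opposing batch mean).  PSNR
(10·log₁₀(MAX²/MSE)) and windowed SSIM are reported per plane as
mean ± std over slices; LPIPS is a plug-in seam for a user-supplied scorer.
The classical baseline — filling missing voxels with the mean of their known
face-adjacent neighbors — ships as `interpolation_repair`.

Everything runs on synthetic brain-like phantoms (Gaussian-ellipsoid
anatomy + band-limited texture + acquisition noise), so the full pipeline is
testable without any dataset download.  The networks, losses and training
loop run on a small numpy autodiff backend (`trisr.nn`); see
`docs/methods.md` for the model details and numerical choices.

## Worked example

Generate a phantom, decimate and rebuild it tri-planarly, then run the
two-pass reconstruction against a simulated half-resolution input:

```sh
trisr phantom --shape 64,64,38 --n 1 --seed 7 --out work/vols
trisr rebuild --volume work/vols/phantom_0007.nii.gz --interval 1 \
      --repair volume --out work/rebuild
trisr reconstruct --volume work/vols/phantom_0007.nii.gz \
      --identity-init --simulate --out work/recon
```

The rebuild step prints

```
missing fraction: 0.125000
```

— the 1/8 of voxels no decimated plane covers.  The reconstruct step
downscales the phantom ×2 (to 32 × 32 × 19), runs both passes with
identity-initialized generators (which reduce to bicubic upscaling + an
identity restoration pass), and evaluates against the original:

```
# reconstruction vs truth (dynamic range MAX_I=1.0, std over slices)
plane     metric  mean +/- std                n
sagittal  psnr    29.9696 +/- 10.6401        64
sagittal  ssim    0.8140 +/- 0.1755          64
coronal   psnr    31.8847 +/- 11.0994        64
coronal   ssim    0.8139 +/- 0.1970          64
axial     psnr    27.8405 +/- 10.1271        38
axial     ssim    0.8102 +/- 0.1595          38
```

(The large slice-to-slice std is expected on phantoms: near-empty border
slices score far higher than textured central ones.)  This PSNR is the
interpolation floor that trained generators improve on;
`trisr train-stage1` / `trisr train-gan` produce checkpoints that
`trisr reconstruct --g1-ckpt ... --g2-ckpt ...` consumes.  Every
artifact-producing command writes a JSON run manifest (options, input
hashes, outputs, versions) next to its outputs.

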