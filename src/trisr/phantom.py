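"""Synthetic brain-like phantom volumes.

Real T1 head volumes are large and not redistributable, so every stage of the
pipeline is exercised on synthetic phantoms: a dark background containing a
smooth "anatomical" foreground built from random Gaussian ellipsoids, an
additive band-limited texture field (the high-frequency content the
super-resolution networks must learn to restore), and mild Gaussian
acquisition noise.  Intensities are clipped to [0, 1] and generation is fully
deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import Volume, write_volume

FULL_SHAPE = (256, 256, 150)   # native T1 grid emulated by default
SMALL_SHAPE = (64, 64, 38)     # small-test default; halves to odd z like 150->75


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = FULL_SHAPE
    n_blobs: int = 12
    texture_scale: float = 3.0   # voxels; spatial scale of the band-limited texture
    texture_amp: float = 0.08
    noise_sigma: float = 0.01    # std of additive Gaussian noise on the [0,1] scale
    seed: int = 0

    def validate(self):
        if len(self.shape) != 3:
            raise ValueError("phantom shape must be a 3-tuple")
        if any(int(s) < 8 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 8, got {self.shape}")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        if self.noise_sigma < 0 or self.texture_amp < 0:
            raise ValueError("noise_sigma and texture_amp must be >= 0")


def generate_phantom(spec: PhantomSpec) -> Volume:
    """Render a phantom volume from its spec (bit-deterministic under seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    nx, ny, nz = shape
    vol = np.zeros(shape)

    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij", sparse=True)
    for _ in range(spec.n_blobs):
        # centers kept in the interior so the border stays near-zero background
        c = rng.uniform([0.25 * nx, 0.25 * ny, 0.25 * nz],
                        [0.75 * nx, 0.75 * ny, 0.75 * nz])
        sig = rng.uniform([0.06 * nx, 0.06 * ny, 0.06 * nz],
                          [0.18 * nx, 0.18 * ny, 0.18 * nz])
        amp = rng.uniform(0.3, 0.9)
        vol += amp * np.exp(-(((x - c[0]) / sig[0]) ** 2
                              + ((y - c[1]) / sig[1]) ** 2
                              + ((z - c[2]) / sig[2]) ** 2) / 2.0)

    envelope = np.clip(vol / max(vol.max(), 1e-12), 0.0, 1.0) if spec.n_blobs else 0.0

    if spec.texture_amp > 0 and spec.n_blobs > 0:
        # band-limited texture: difference of Gaussian-smoothed white noise,
        # confined to the foreground by the blob envelope
        white = rng.standard_normal(shape)
        s = max(spec.texture_scale, 0.5)
        band = (ndimage.gaussian_filter(white, s / 2.0)
                - ndimage.gaussian_filter(white, s))
        band /= max(band.std(), 1e-12)
        vol += spec.texture_amp * band * envelope

    if spec.noise_sigma > 0:
        vol += rng.normal(0.0, spec.noise_sigma, size=shape)

    return Volume(np.clip(vol, 0.0, 1.0))


def make_fixture_set(spec: PhantomSpec, n: int, out_dir) -> list[Path]:
    """Write ``n`` phantom volumes (seeds spec.seed..spec.seed+n-1) + manifest."""
    if n < 1:
        raise ValueError("fixture set size must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths, rows = [], []
    for i in range(n):
        sub = PhantomSpec(shape=spec.shape, n_blobs=spec.n_blobs,
                          texture_scale=spec.texture_scale,
                          texture_amp=spec.texture_amp,
                          noise_sigma=spec.noise_sigma, seed=spec.seed + i)
        vol = generate_phantom(sub)
        path = out_dir / f"phantom_{sub.seed:04d}.nii.gz"
        write_volume(vol, path)
        paths.append(path)
        rows.append({"file": path.name, "seed": sub.seed,
                     "shape": list(sub.shape)})
    (out_dir / "manifest.json").write_text(
        json.dumps({"phantoms": rows}, indent=2))
    return paths
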