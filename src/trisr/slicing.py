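"""Tri-planar slice extraction, decimation, degradation and patch pairing.

The acquisition protocol emulated here: a volume is sliced along each of the
three anatomical planes; every other slice is kept ("interval of 1 slice",
i.e. keep one, skip one, starting at index 0, so even source indices
survive); kept high-resolution slices are degraded by bicubic downscaling to
form the low-resolution inputs; and paired LR/HR patches (16x16 / 32x32 by
default) are tiled from the slices as the training unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .resample import downscale_2d
from .volume_io import PLANE_AXIS, PLANES, Volume

log = logging.getLogger(__name__)


@dataclass
class SliceStack:
    """An ordered set of 2-D slices from one anatomical plane."""

    plane: str
    slices: list[np.ndarray]
    source_indices: list[int]
    source_shape: tuple[int, int, int]

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")
        if len(self.slices) != len(self.source_indices):
            raise ValueError("slices and source_indices lengths differ")
        if not self.slices:
            raise ValueError("empty slice stack")
        axis = PLANE_AXIS[self.plane]
        expected = tuple(s for i, s in enumerate(self.source_shape) if i != axis)
        for sl in self.slices:
            if sl.shape != expected:
                raise ValueError(
                    f"slice shape {sl.shape} inconsistent with plane "
                    f"{self.plane} of volume {self.source_shape}")
        idx = self.source_indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("source_indices must be strictly increasing")
        if idx[-1] >= self.source_shape[axis] or idx[0] < 0:
            raise ValueError("source index outside the volume extent")

    @property
    def axis(self) -> int:
        return PLANE_AXIS[self.plane]

    def __len__(self):
        return len(self.slices)


@dataclass
class PatchPair:
    """One LR/HR training pair; hr side == lr side * scale."""

    lr: np.ndarray
    hr: np.ndarray
    origin: tuple[int, int, int]   # (slice id, row, col) in HR coordinates
    scale: int = 2

    def __post_init__(self):
        if self.hr.shape != tuple(s * self.scale for s in self.lr.shape):
            raise ValueError("hr patch must be lr patch upscaled by the pair scale")


def extract_slices(vol: Volume, plane: str) -> SliceStack:
    """One slice per index along the plane's axis, in source order."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {PLANES}")
    axis = PLANE_AXIS[plane]
    n = vol.shape[axis]
    slices = [np.take(vol.voxels, i, axis=axis).copy() for i in range(n)]
    return SliceStack(plane=plane, slices=slices,
                      source_indices=list(range(n)), source_shape=vol.shape)


def restack(stack: SliceStack) -> Volume:
    """Inverse of :func:`extract_slices` for a full (undecimated) stack."""
    axis = stack.axis
    if stack.source_indices != list(range(stack.source_shape[axis])):
        raise ValueError("restack requires a full stack; use reassembly.rebuild "
                         "for partial stacks")
    vox = np.stack(stack.slices, axis=axis)
    return Volume(vox)


def decimate(stack: SliceStack, interval: int = 1) -> SliceStack:
    """Keep one slice, skip ``interval`` slices: positions 0, interval+1, ...

    Source indices are preserved from the original volume, so the decimated
    stack still knows where each slice belongs.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    step = interval + 1
    keep = list(range(0, len(stack.slices), step))
    return SliceStack(plane=stack.plane,
                      slices=[stack.slices[i] for i in keep],
                      source_indices=[stack.source_indices[i] for i in keep],
                      source_shape=stack.source_shape)


def degrade_slice(hr_slice: np.ndarray, scale: int = 2) -> np.ndarray:
    """Bicubic degradation: downscale by ``scale`` to ceil(dim/scale)."""
    hr_slice = np.asarray(hr_slice, dtype=np.float64)
    if hr_slice.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got ndim={hr_slice.ndim}")
    if min(hr_slice.shape) < scale:
        raise ValueError("slice smaller than the degradation factor")
    return downscale_2d(hr_slice, scale, kernel="cubic")


def degrade_stack(stack: SliceStack, scale: int = 2) -> SliceStack:
    """Apply :func:`degrade_slice` to every slice of a stack."""
    small = [np.clip(degrade_slice(s, scale), 0.0, 1.0) for s in stack.slices]
    lo_shape = list(stack.source_shape)
    for i in range(3):
        if i != stack.axis:
            lo_shape[i] = -(-lo_shape[i] // scale)
    return SliceStack(plane=stack.plane, slices=small,
                      source_indices=list(stack.source_indices),
                      source_shape=tuple(lo_shape))


def make_patch_pairs(stack: SliceStack, lr_size: int = 16, scale: int = 2,
                     stride: int | None = None,
                     degrade_mode: str = "patch") -> list[PatchPair]:
    """Tile HR patches from every slice and pair each with its degradation.

    ``degrade_mode='patch'`` degrades each HR crop independently, so the pair
    is aligned exactly at patch borders.  ``degrade_mode='slice'`` degrades
    the whole slice once and crops the LR patch from it, matching the
    operator seen by whole-slice inference (boundary taps then come from
    neighboring patches, as they do at test time).  Slices smaller than one
    HR patch are skipped with a warning.
    """
    hr_size = lr_size * scale
    if stride is None:
        stride = hr_size
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if degrade_mode not in ("patch", "slice"):
        raise ValueError(f"unknown degrade_mode {degrade_mode!r}")
    if degrade_mode == "slice" and stride % scale != 0:
        raise ValueError("slice-level degradation requires a stride that is "
                         "a multiple of the scale")
    pairs: list[PatchPair] = []
    for sid, sl in zip(stack.source_indices, stack.slices):
        h, w = sl.shape
        if h < hr_size or w < hr_size:
            log.warning("slice %d (%dx%d) smaller than one %dx%d patch; skipped",
                        sid, h, w, hr_size, hr_size)
            continue
        lr_full = (np.clip(degrade_slice(sl, scale), 0.0, 1.0)
                   if degrade_mode == "slice" else None)
        for r in range(0, h - hr_size + 1, stride):
            for c in range(0, w - hr_size + 1, stride):
                hr = sl[r:r + hr_size, c:c + hr_size].copy()
                if degrade_mode == "patch":
                    lr = np.clip(degrade_slice(hr, scale), 0.0, 1.0)
                else:
                    lr = lr_full[r // scale:r // scale + lr_size,
                                 c // scale:c // scale + lr_size].copy()
                pairs.append(PatchPair(lr=lr, hr=hr, origin=(sid, r, c),
                                       scale=scale))
    return pairs


def split_dataset(ids: list, train_count: int, seed: int = 0) -> tuple[list, list]:
    """Deterministic seeded shuffle then a (train_count, rest) partition."""
    if not 0 < train_count < len(ids):
        raise ValueError(f"train_count must be in (0, {len(ids)}), got {train_count}")
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    return shuffled[:train_count], shuffled[train_count:]


# -- PNG export -------------------------------------------------------------

def save_slice_png(sl: np.ndarray, path, bit_depth: int = 16) -> None:
    """Save a [0,1] slice as 8- or 16-bit grayscale PNG."""
    sl = np.clip(np.asarray(sl, dtype=np.float64), 0.0, 1.0)
    if bit_depth == 16:
        arr = np.round(sl * 65535).astype(np.uint16)
        img = Image.fromarray(arr)
    elif bit_depth == 8:
        img = Image.fromarray(np.round(sl * 255).astype(np.uint8), mode="L")
    else:
        raise ValueError("bit_depth must be 8 or 16")
    img.save(str(path))


def export_stack(stack: SliceStack, out_dir, split: str = "train",
                 volume_id: str = "vol", bit_depth: int = 16) -> Path:
    """Write slices as ``<split>/<plane>/<volume_id>/<idx>.png`` + JSON index."""
    base = Path(out_dir) / split / stack.plane / volume_id
    base.mkdir(parents=True, exist_ok=True)
    files = []
    for sid, sl in zip(stack.source_indices, stack.slices):
        p = base / f"{sid:04d}.png"
        save_slice_png(sl, p, bit_depth)
        files.append(p.name)
    index = {"plane": stack.plane, "source_shape": list(stack.source_shape),
             "source_indices": list(stack.source_indices), "files": files,
             "bit_depth": bit_depth}
    (base / "index.json").write_text(json.dumps(index, indent=2))
    return base
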