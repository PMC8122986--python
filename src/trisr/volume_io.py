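"""NIfTI volume I/O, intensity normalization and the canonical axis order.

A :class:`Volume` is a 3-D voxel grid with intensities min-max normalized to
[0, 1] per volume and the raw range retained so intensities can be recovered.
Axes follow the fixed convention (x = sagittal index, y = coronal index,
z = axial index).  On read, the NIfTI affine's nearest axis permutation is
applied (no resampling) so stored volumes of any orientation land on the same
grid convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

PLANES = ("sagittal", "coronal", "axial")
PLANE_AXIS = {"sagittal": 0, "coronal": 1, "axial": 2}


@dataclass
class Volume:
    """A normalized 3-D intensity grid plus its raw intensity range."""

    voxels: np.ndarray
    norm: tuple[float, float] = (0.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume must be 3-D, got ndim={self.voxels.ndim}")
        if np.isnan(self.voxels).any():
            raise ValueError("Volume contains NaN voxels")
        if self.voxels.size and (self.voxels.min() < -1e-9
                                 or self.voxels.max() > 1 + 1e-9):
            raise ValueError("Volume intensities must lie in [0, 1]; "
                             "use normalize() on raw data first")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def denormalize(self) -> np.ndarray:
        lo, hi = self.norm
        return self.voxels * (hi - lo) + lo

    def __eq__(self, other):
        return (isinstance(other, Volume)
                and self.shape == other.shape
                and np.array_equal(self.voxels, other.voxels))


def normalize(raw: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Per-volume min-max scaling to [0, 1]; constant volumes map to zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        log.warning("constant volume: normalization degenerates to all zeros")
        return np.zeros_like(raw), (lo, hi)
    return (raw - lo) / (hi - lo), (lo, hi)


_NORM_TAG = "trisrnorm"


def _parse_norm_header(img) -> tuple[float, float] | None:
    try:
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(
            "ascii", "ignore")
    except Exception:
        return None
    if not descrip.startswith(_NORM_TAG):
        return None
    try:
        _, lo, hi = descrip.split()[:3]
        return float(lo), float(hi)
    except ValueError:
        return None


def read_volume(path, do_normalize: bool = True) -> Volume:
    """Load a NIfTI file into the canonical axis convention."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI image, got ndim={data.ndim}")
    if np.isnan(data).any():
        raise ValueError(f"NIfTI volume {path} contains NaN voxels")
    # nearest axis permutation from the affine; never resamples
    ornt = nib.orientations.io_orientation(img.affine)
    data = nib.orientations.apply_orientation(data, ornt)
    affine = img.affine @ nib.orientations.inv_ornt_aff(ornt, data.shape)
    stored_norm = _parse_norm_header(img)
    if do_normalize:
        if stored_norm is not None:
            # a range recorded at write time takes precedence over the data
            # min/max so write -> read round trips are exact
            lo, hi = stored_norm
            vox = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
            norm = stored_norm
        else:
            vox, norm = normalize(data)
    else:
        vox, norm = data, (0.0, 1.0)
        if vox.size and (vox.min() < 0 or vox.max() > 1):
            raise ValueError("raw intensities outside [0,1]; "
                             "rerun without --no-normalize")
    return Volume(vox, norm=norm, affine=affine)


def write_volume(vol: Volume, path) -> None:
    """Write a Volume as NIfTI, storing raw (denormalized) intensities."""
    raw = vol.denormalize()
    if np.isnan(raw).any():
        raise ValueError("refusing to write volume with NaN voxels")
    img = nib.Nifti1Image(raw.astype(np.float64), vol.affine)
    lo, hi = vol.norm
    img.header["descrip"] = f"{_NORM_TAG} {lo:.17g} {hi:.17g}".encode("ascii")
    nib.save(img, str(path))


def downscale_volume(vol: Volume, factor: int) -> Volume:
    """Simulate the half-resolution acquisition by 3-D cubic-spline zoom.

    Each dimension becomes ceil(dim/factor).
    """
    if factor < 2:
        raise ValueError("downscale factor must be >= 2")
    out_shape = tuple(ceil(d / factor) for d in vol.shape)
    zoom = [o / i for o, i in zip(out_shape, vol.shape)]
    small = ndimage.zoom(vol.voxels, zoom, order=3, mode="reflect",
                         grid_mode=True, prefilter=True)
    assert small.shape == out_shape
    return Volume(np.clip(small, 0.0, 1.0), norm=vol.norm, affine=vol.affine)
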