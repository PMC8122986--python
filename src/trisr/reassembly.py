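"""Rebuild a 3-D volume from tri-planar slice stacks.

When the three planes contribute only every other slice, a voxel is written
by the sagittal stack iff its x index is even, by the coronal stack iff y is
even, and by the axial stack iff z is even; a voxel with all three
coordinates odd is written by no plane.  On even-dimension volumes exactly
1/8 of the voxels are therefore missing.  The rebuild keeps an explicit
per-voxel contribution count and missing mask (the sentinel value 0 is never
used for detection, since 0 is a legal intensity), and the classical
linear-interpolation repair of missing voxels is provided as the baseline
restoration method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .slicing import SliceStack
from .volume_io import PLANE_AXIS, Volume

MISSING_SENTINEL = 0.0


@dataclass
class ReassembledVolume:
    voxels: np.ndarray
    contrib_count: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        if not (self.voxels.shape == self.contrib_count.shape
                == self.missing_mask.shape):
            raise ValueError("field shapes differ")
        if self.contrib_count.min() < 0 or self.contrib_count.max() > 3:
            raise ValueError("contrib_count must lie in {0,1,2,3}")
        if not np.array_equal(self.missing_mask, self.contrib_count == 0):
            raise ValueError("missing_mask inconsistent with contrib_count")

    @property
    def shape(self):
        return self.voxels.shape


def rebuild(stacks: list[SliceStack], target_shape: tuple[int, int, int],
            merge: str = "mean") -> ReassembledVolume:
    """Write each stack's slices at their source indices and merge overlaps.

    ``merge='mean'`` averages the contributions of the planes that wrote a
    voxel (order-independent); ``merge='priority'`` lets axial overwrite
    coronal overwrite sagittal.
    """
    if merge not in ("mean", "priority"):
        raise ValueError(f"unknown merge rule {merge!r}")
    planes = [s.plane for s in stacks]
    if len(set(planes)) != len(planes):
        raise ValueError(f"duplicate planes in stacks: {planes}")
    target_shape = tuple(int(s) for s in target_shape)

    acc = np.zeros(target_shape)
    count = np.zeros(target_shape, dtype=np.int16)
    first = np.zeros(target_shape)   # first-written value per voxel
    mixed = np.zeros(target_shape, dtype=bool)
    # priority order: later writes win under 'priority'
    order = {"sagittal": 0, "coronal": 1, "axial": 2}
    for stack in sorted(stacks, key=lambda s: order[s.plane]):
        axis = PLANE_AXIS[stack.plane]
        expected = tuple(s for i, s in enumerate(target_shape) if i != axis)
        for sid, sl in zip(stack.source_indices, stack.slices):
            if sl.shape != expected:
                raise ValueError(
                    f"{stack.plane} slice shape {sl.shape} does not match "
                    f"target {target_shape}")
            if sid >= target_shape[axis]:
                raise ValueError(
                    f"{stack.plane} source index {sid} outside target extent "
                    f"{target_shape[axis]}")
            idx = [slice(None)] * 3
            idx[axis] = sid
            idx = tuple(idx)
            if merge == "mean":
                acc[idx] += sl
                seen = count[idx] > 0
                mixed[idx] |= seen & (first[idx] != sl)
                first[idx] = np.where(seen, first[idx], sl)
            else:
                acc[idx] = sl
            count[idx] += 1

    missing = count == 0
    if merge == "mean":
        # voxels where every contributing plane agreed keep that value
        # bit-exactly; only genuinely disagreeing voxels are averaged
        mean = acc / np.maximum(count, 1)
        vox = np.where(missing, MISSING_SENTINEL,
                       np.where(mixed, mean, first))
    else:
        vox = np.where(missing, MISSING_SENTINEL, acc)
    return ReassembledVolume(voxels=vox, contrib_count=count,
                             missing_mask=missing)


def missing_fraction(rv: ReassembledVolume) -> float:
    """count(missing voxels) / total voxels."""
    return float(rv.missing_mask.mean())


def _fill_pass(vox: np.ndarray, known: np.ndarray,
               axes: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    nb_sum = np.zeros_like(vox)
    nb_cnt = np.zeros(vox.shape)
    for axis in axes:
        for shift in (1, -1):
            shifted_v = np.roll(vox, shift, axis=axis)
            shifted_k = np.roll(known, shift, axis=axis)
            # np.roll wraps around; zero the wrapped border
            edge = [slice(None)] * vox.ndim
            edge[axis] = 0 if shift == 1 else -1
            shifted_k = shifted_k.copy()
            shifted_k[tuple(edge)] = False
            nb_sum += np.where(shifted_k, shifted_v, 0.0)
            nb_cnt += shifted_k
    fillable = (~known) & (nb_cnt > 0)
    newv = vox.copy()
    newv[fillable] = nb_sum[fillable] / nb_cnt[fillable]
    return newv, known | fillable


def interpolation_repair(rv: ReassembledVolume, mode: str = "volume",
                         slice_axis: int = 2) -> Volume:
    """Baseline repair: fill each missing voxel with the mean of its known
    face-adjacent neighbors, iterating until no missing voxels remain.

    ``mode='volume'`` uses the 6-connected 3-D neighborhood; ``mode='slice'``
    restricts neighbors to the 4-connected in-plane neighborhood of the slices
    along ``slice_axis``, matching a purely slice-wise restoration.
    """
    if mode not in ("volume", "slice"):
        raise ValueError(f"unknown repair mode {mode!r}")
    known = ~rv.missing_mask
    if not known.any():
        raise ValueError("cannot repair an all-missing volume")
    vox = rv.voxels.copy()
    axes = (0, 1, 2) if mode == "volume" else tuple(
        a for a in (0, 1, 2) if a != slice_axis)
    if mode == "slice":
        # a slice with no known voxel can never be filled slice-wise
        sl_known = known.any(axis=axes[0]).any(axis=axes[1] - 1)
        if not sl_known.all():
            raise ValueError("slice-wise repair impossible: some slices along "
                             f"axis {slice_axis} contain no known voxels")
    while not known.all():
        vox, new_known = _fill_pass(vox, known, axes)
        if new_known.sum() == known.sum():
            raise RuntimeError("repair stalled with unfillable voxels")
        known = new_known
    return Volume(np.clip(vox, 0.0, 1.0))
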