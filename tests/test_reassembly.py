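"""Tri-planar rebuild: round trips, missing-voxel structure, baseline repair."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisr.phantom import PhantomSpec, generate_phantom
from trisr.reassembly import (ReassembledVolume, interpolation_repair,
                              missing_fraction, rebuild)
from trisr.slicing import decimate, extract_slices
from trisr.volume_io import PLANES, Volume


def triplanar_stacks(vol, interval=None):
    stacks = [extract_slices(vol, p) for p in PLANES]
    if interval is not None:
        stacks = [decimate(s, interval) for s in stacks]
    return stacks


def enumerate_missing(shape, kept_indices_by_plane):
    """Brute-force oracle: a voxel is missing iff no plane's kept slice set
    contains the corresponding coordinate."""
    missing = 0
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                covered = (x in kept_indices_by_plane[0]
                           or y in kept_indices_by_plane[1]
                           or z in kept_indices_by_plane[2])
                missing += not covered
    return missing / np.prod(shape)


def test_full_triplanar_rebuild_is_bit_exact_identity():
    for seed in range(20):
        vol = generate_phantom(PhantomSpec(shape=(12, 14, 10), n_blobs=3,
                                           seed=seed))
        rv = rebuild(triplanar_stacks(vol), vol.shape)
        assert np.array_equal(rv.voxels, vol.voxels)
        assert missing_fraction(rv) == 0.0
        assert rv.contrib_count.min() == 3


def test_interval1_missing_fraction_is_one_eighth(small_phantom):
    rv = rebuild(triplanar_stacks(small_phantom, interval=1),
                 small_phantom.shape)
    assert missing_fraction(rv) == pytest.approx(1.0 / 8.0)
    # missing voxels are exactly those with all-odd coordinates
    x, y, z = np.meshgrid(*(np.arange(s) for s in small_phantom.shape),
                          indexing="ij", sparse=True)
    assert np.array_equal(rv.missing_mask, (x % 2 == 1) & (y % 2 == 1)
                          & (z % 2 == 1))


@settings(deadline=None, max_examples=10, derandomize=True)
@given(shape=st.tuples(st.integers(6, 12), st.integers(6, 12),
                       st.integers(6, 12)),
       interval=st.integers(1, 3))
def test_missing_fraction_matches_enumeration_oracle(shape, interval):
    vol = Volume(np.random.default_rng(0).random(shape))
    stacks = triplanar_stacks(vol, interval=interval)
    rv = rebuild(stacks, shape)
    kept = [set(s.source_indices) for s in stacks]
    assert missing_fraction(rv) == pytest.approx(
        enumerate_missing(shape, kept))


def test_axial_only_even_rebuild_has_half_missing(small_phantom):
    stack = decimate(extract_slices(small_phantom, "axial"), 1)
    rv = rebuild([stack], small_phantom.shape)
    assert missing_fraction(rv) == pytest.approx(0.5)
    assert rv.voxels[rv.missing_mask].max() == 0.0  # sentinel before repair


def test_merge_is_order_independent(small_phantom):
    stacks = triplanar_stacks(small_phantom, interval=1)
    a = rebuild(stacks, small_phantom.shape)
    b = rebuild(stacks[::-1], small_phantom.shape)
    assert np.array_equal(a.voxels, b.voxels)
    assert np.array_equal(a.contrib_count, b.contrib_count)


def test_duplicate_or_mismatched_stacks_rejected(small_phantom):
    s = decimate(extract_slices(small_phantom, "axial"), 1)
    with pytest.raises(ValueError, match="duplicate"):
        rebuild([s, s], small_phantom.shape)
    with pytest.raises(ValueError):
        rebuild([s], (10, 10, 10))


def test_priority_merge_lets_axial_win():
    vol = Volume(np.full((6, 6, 6), 0.25))
    sag = extract_slices(vol, "sagittal")
    axial = extract_slices(Volume(np.full((6, 6, 6), 0.75)), "axial")
    rv = rebuild([sag, axial], (6, 6, 6), merge="priority")
    assert np.all(rv.voxels == 0.75)
    rv_mean = rebuild([sag, axial], (6, 6, 6), merge="mean")
    assert np.allclose(rv_mean.voxels, 0.5)


# -- interpolation repair ---------------------------------------------------

def test_repair_with_no_missing_is_identity(small_phantom):
    rv = rebuild(triplanar_stacks(small_phantom), small_phantom.shape)
    out = interpolation_repair(rv)
    assert np.array_equal(out.voxels, small_phantom.voxels)


def test_single_missing_voxel_filled_with_neighbor_mean():
    vox = np.full((5, 5, 5), 0.5)
    count = np.full((5, 5, 5), 1, dtype=np.int16)
    vox[2, 2, 2] = 0.0
    count[2, 2, 2] = 0
    rv = ReassembledVolume(vox, count, count == 0)
    out = interpolation_repair(rv)
    assert out.voxels[2, 2, 2] == pytest.approx(0.5)


def test_repair_of_constant_decimated_volume_is_constant():
    vol = Volume(np.full((8, 8, 8), 0.7))
    rv = rebuild(triplanar_stacks(vol, interval=1), vol.shape)
    out = interpolation_repair(rv)
    assert np.allclose(out.voxels, 0.7, atol=1e-12)


def test_repair_never_alters_known_voxels(small_phantom):
    rv = rebuild(triplanar_stacks(small_phantom, interval=1),
                 small_phantom.shape)
    out = interpolation_repair(rv)
    known = ~rv.missing_mask
    assert np.array_equal(out.voxels[known], small_phantom.voxels[known])
    assert np.isfinite(out.voxels).all()


def test_repair_terminates_from_a_single_known_voxel():
    vox = np.zeros((4, 4, 4))
    count = np.zeros((4, 4, 4), dtype=np.int16)
    vox[0, 0, 0] = 0.9
    count[0, 0, 0] = 1
    out = interpolation_repair(ReassembledVolume(vox, count, count == 0))
    assert np.allclose(out.voxels, 0.9)


def test_repair_rejects_all_missing():
    count = np.zeros((4, 4, 4), dtype=np.int16)
    with pytest.raises(ValueError):
        interpolation_repair(ReassembledVolume(np.zeros((4, 4, 4)), count,
                                               count == 0))


def test_slicewise_repair_stays_in_plane():
    # known voxels only on even axial slices; slice-wise repair along z must
    # fail for odd slices (they contain no known voxel), volumetric succeeds
    vox = np.zeros((4, 4, 4))
    count = np.zeros((4, 4, 4), dtype=np.int16)
    vox[:, :, ::2] = 0.3
    count[:, :, ::2] = 1
    rv = ReassembledVolume(vox, count, count == 0)
    assert np.allclose(interpolation_repair(rv, mode="volume").voxels, 0.3)
    with pytest.raises(ValueError, match="slice-wise"):
        interpolation_repair(rv, mode="slice", slice_axis=2)
    # slicing along x instead: every x-slice has known voxels
    out = interpolation_repair(rv, mode="slice", slice_axis=0)
    assert np.allclose(out.voxels, 0.3)
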