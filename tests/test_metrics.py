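"""Unit and property tests for the pairwise agreement metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oarconcord import (
    EmptyMaskError,
    GridMismatchError,
    ImageGrid,
    Status,
    StructureMask,
    compare,
    dice,
    directed_distances,
    extract_surface,
    hd95,
    msd,
    msd_directed,
    pooled_surface_distances,
    volume_cc,
)

from conftest import (
    box_mask,
    make_mask,
    oracle_dice,
    oracle_directed,
    oracle_hd95,
    oracle_msd,
    oracle_pooled,
    oracle_surface_points,
    random_blob_mask,
)


class TestDice:
    def test_identical_masks_give_one(self, rng):
        a = random_blob_mask(rng, (12, 12, 12))
        assert dice(a, a) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = box_mask((20, 20, 20), (0, 0, 0), (5, 5, 5))
        b = box_mask((20, 20, 20), (10, 10, 10), (15, 15, 15))
        assert dice(a, b) == 0.0

    def test_half_shifted_cube(self):
        # 10^3 cube against itself shifted +5 voxels in x: overlap 500,
        # 2*500/(1000+1000) = 0.5 exactly
        a = box_mask((20, 20, 20), (0, 5, 5), (10, 15, 15))
        b = box_mask((20, 20, 20), (5, 5, 5), (15, 15, 15))
        assert dice(a, b) == 0.5

    def test_both_empty_is_undefined(self):
        empty = make_mask(np.zeros((5, 5, 5)))
        with pytest.raises(EmptyMaskError):
            dice(empty, empty)

    def test_grid_mismatch_rejected(self):
        a = box_mask((10, 10, 10), (2, 2, 2), (5, 5, 5), spacing=(1, 1, 3))
        b = box_mask((10, 10, 10), (2, 2, 2), (5, 5, 5), spacing=(1, 1, 2.5))
        with pytest.raises(GridMismatchError):
            dice(a, b)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        occ_a=arrays(bool, (5, 5, 5)),
        occ_b=arrays(bool, (5, 5, 5)),
    )
    def test_symmetry_and_bounds_property(self, occ_a, occ_b):
        if not (occ_a.any() or occ_b.any()):
            return
        a, b = make_mask(occ_a), make_mask(occ_b)
        d_ab, d_ba = dice(a, b), dice(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0


class TestSurfaceExtraction:
    @pytest.mark.parametrize(
        "side,expected",
        [(1, 1), (3, 26), (5, 98)],  # n^3 - (n-2)^3 interior voxels removed
    )
    def test_solid_cube_boundary_count(self, side, expected):
        m = box_mask((side + 4, side + 4, side + 4), (2, 2, 2), (2 + side,) * 3)
        assert extract_surface(m).count == expected

    def test_empty_mask_gives_empty_surface(self):
        assert extract_surface(make_mask(np.zeros((4, 4, 4)))).count == 0

    def test_volume_edge_counts_as_boundary(self):
        # a slab filling the whole grid still has a surface (cropped structure)
        m = make_mask(np.ones((4, 4, 4)))
        assert extract_surface(m).count == 4**3 - 2**3

    def test_matches_oracle_on_random_blobs(self, rng):
        for _ in range(5):
            m = random_blob_mask(rng, (15, 15, 15), spacing=(0.9, 1.1, 2.0))
            got = extract_surface(m).points
            want = oracle_surface_points(m)
            assert got.shape == want.shape
            np.testing.assert_array_equal(
                got[np.lexsort(got.T)], want[np.lexsort(want.T)]
            )


class TestDirectedDistances:
    def test_subset_gives_zeros(self, rng):
        m = random_blob_mask(rng, (10, 10, 10))
        s = extract_surface(m)
        np.testing.assert_array_equal(directed_distances(s, s), np.zeros(s.count))

    def test_anisotropic_spacing_in_mm(self):
        # two single voxels 3 slices apart at 3 mm slice thickness: 9 mm
        occ_a = np.zeros((5, 5, 8), bool)
        occ_b = np.zeros((5, 5, 8), bool)
        occ_a[2, 2, 1] = True
        occ_b[2, 2, 4] = True
        a = make_mask(occ_a, spacing=(1, 1, 3))
        b = make_mask(occ_b, spacing=(1, 1, 3))
        d = directed_distances(extract_surface(a), extract_surface(b))
        np.testing.assert_array_equal(d, [9.0])

    def test_empty_target_rejected(self, rng):
        m = random_blob_mask(rng, (8, 8, 8))
        empty = extract_surface(make_mask(np.zeros((8, 8, 8))))
        with pytest.raises(EmptyMaskError):
            directed_distances(extract_surface(m), empty)

    def test_matches_brute_force_exactly(self, rng):
        for _ in range(10):
            a = random_blob_mask(rng, (15, 15, 15))
            b = random_blob_mask(rng, (15, 15, 15))
            sa, sb = extract_surface(a), extract_surface(b)
            got = directed_distances(sa, sb)
            want = oracle_directed(sa.points, sb.points)
            np.testing.assert_array_equal(got, want)


class TestSurfaceDistanceMetrics:
    def test_msd_identity_is_zero(self, rng):
        m = random_blob_mask(rng, (10, 10, 10))
        assert msd(m, m) == 0.0
        assert hd95(m, m) == 0.0

    def test_parallel_plates(self):
        # two aligned 1-voxel-thick 10x10 plates 3 slices apart at unit
        # spacing: every pooled distance is exactly 3, so MSD = HD95 = 3.0
        occ_a = np.zeros((12, 12, 6), bool)
        occ_b = np.zeros((12, 12, 6), bool)
        occ_a[1:11, 1:11, 0] = True
        occ_b[1:11, 1:11, 3] = True
        a, b = make_mask(occ_a), make_mask(occ_b)
        assert msd(a, b) == 3.0
        assert hd95(a, b) == 3.0

    def test_dilated_cube_matches_oracle(self):
        from scipy import ndimage

        occ = np.zeros((26, 26, 26), bool)
        occ[3:23, 3:23, 3:23] = True
        cube = make_mask(occ)
        dilated = make_mask(ndimage.binary_dilation(occ))
        assert msd(cube, dilated) == pytest.approx(oracle_msd(cube, dilated), abs=0)
        assert hd95(cube, dilated) == pytest.approx(oracle_hd95(cube, dilated), abs=0)

    def test_spike_hd95_below_max(self):
        occ = np.zeros((20, 20, 20), bool)
        occ[5:15, 5:15, 5:15] = True
        cube = make_mask(occ)
        spiked = occ.copy()
        spiked[9, 9, 15:20] = True  # 1x1x5 protruding spike
        spike_mask = make_mask(spiked)
        pooled = pooled_surface_distances(cube, spike_mask)
        assert hd95(cube, spike_mask) < pooled.max()
        assert hd95(cube, spike_mask) == pytest.approx(oracle_hd95(cube, spike_mask), abs=0)
        assert msd(cube, spike_mask) == pytest.approx(oracle_msd(cube, spike_mask), abs=0)

    def test_symmetry(self, rng):
        for _ in range(5):
            a = random_blob_mask(rng, (12, 12, 12), spacing=(1, 1, 2))
            b = random_blob_mask(rng, (12, 12, 12), spacing=(1, 1, 2))
            assert msd(a, b) == msd(b, a)
            assert hd95(a, b) == hd95(b, a)

    def test_translation_invariance(self, rng):
        a = random_blob_mask(rng, (14, 14, 14))
        b = random_blob_mask(rng, (14, 14, 14))
        occ_a = np.zeros((20, 20, 20), bool)
        occ_b = np.zeros((20, 20, 20), bool)
        occ_a[:14, :14, :14] = a.occupancy
        occ_b[:14, :14, :14] = b.occupancy
        base_a, base_b = make_mask(occ_a), make_mask(occ_b)
        shifted_a = make_mask(np.roll(occ_a, (3, 2, 4), axis=(0, 1, 2)))
        shifted_b = make_mask(np.roll(occ_b, (3, 2, 4), axis=(0, 1, 2)))
        assert dice(shifted_a, shifted_b) == dice(base_a, base_b)
        assert msd(shifted_a, shifted_b) == msd(base_a, base_b)
        assert hd95(shifted_a, shifted_b) == hd95(base_a, base_b)

    def test_spacing_scaling_linearity(self, rng):
        a1 = random_blob_mask(rng, (12, 12, 12), spacing=(1, 1, 1))
        b1 = random_blob_mask(rng, (12, 12, 12), spacing=(1, 1, 1))
        c = 2.5
        a2 = make_mask(a1.occupancy, spacing=(c, c, c))
        b2 = make_mask(b1.occupancy, spacing=(c, c, c))
        assert dice(a2, b2) == dice(a1, b1)
        assert msd(a2, b2) == pytest.approx(c * msd(a1, b1), rel=1e-12)
        assert hd95(a2, b2) == pytest.approx(c * hd95(a1, b1), rel=1e-12)

    def test_directed_means_average_to_weighted_symmetric(self, rng):
        a = random_blob_mask(rng, (10, 10, 10))
        b = random_blob_mask(rng, (10, 10, 10))
        d_ab, d_ba = msd_directed(a, b)
        na = extract_surface(a).count
        nb = extract_surface(b).count
        assert msd(a, b) == pytest.approx((d_ab * na + d_ba * nb) / (na + nb), rel=1e-12)

    def test_empty_mask_rejected(self, rng):
        m = random_blob_mask(rng, (8, 8, 8))
        empty = make_mask(np.zeros((8, 8, 8)))
        with pytest.raises(EmptyMaskError):
            msd(m, empty)
        with pytest.raises(EmptyMaskError):
            hd95(empty, m)


class TestVolume:
    @pytest.mark.parametrize(
        "n_voxels,spacing,expected_cc",
        [(1000, (1, 1, 1), 1.0), (0, (1, 1, 1), 0.0), (100, (1, 1, 3), 0.3)],
    )
    def test_volume_examples(self, n_voxels, spacing, expected_cc):
        occ = np.zeros((12, 12, 12), bool)
        occ.flat[:n_voxels] = True
        assert volume_cc(make_mask(occ, spacing=spacing)) == pytest.approx(expected_cc)


class TestCompare:
    def test_absent_test_is_not_delineated(self, rng):
        ref = random_blob_mask(rng, (10, 10, 10))
        res = compare(ref, None)
        assert res.status is Status.NOT_DELINEATED
        assert math.isnan(res.dsc) and math.isnan(res.msd_mm) and math.isnan(res.hd95_mm)

    def test_empty_test_scores_dsc_zero(self, rng):
        ref = random_blob_mask(rng, (10, 10, 10))
        res = compare(ref, make_mask(np.zeros((10, 10, 10))))
        assert res.status is Status.TEST_EMPTY
        assert res.dsc == 0.0
        assert math.isnan(res.msd_mm) and math.isnan(res.hd95_mm)

    def test_empty_reference_scores_dsc_zero(self, rng):
        test = random_blob_mask(rng, (10, 10, 10))
        res = compare(make_mask(np.zeros((10, 10, 10))), test)
        assert res.status is Status.REF_EMPTY
        assert res.dsc == 0.0

    def test_both_empty(self):
        empty = make_mask(np.zeros((6, 6, 6)))
        res = compare(empty, make_mask(np.zeros((6, 6, 6))))
        assert res.status is Status.BOTH_EMPTY
        assert math.isnan(res.dsc)

    def test_identical_pair_is_perfect(self, rng):
        ref = random_blob_mask(rng, (10, 10, 10))
        res = compare(ref, ref)
        assert res.status is Status.OK
        assert res.dsc == 1.0
        assert res.msd_mm == 0.0
        assert res.hd95_mm == 0.0
        assert res.volume_ref_cc == res.volume_test_cc == volume_cc(ref)

    def test_ok_pair_consistent_with_elementary_metrics(self, rng):
        a = random_blob_mask(rng, (12, 12, 12), spacing=(1, 1, 2))
        b = random_blob_mask(rng, (12, 12, 12), spacing=(1, 1, 2))
        res = compare(a, b)
        assert res.status is Status.OK
        assert res.dsc == dice(a, b)
        assert res.msd_mm == msd(a, b)
        assert res.hd95_mm == hd95(a, b)
        assert res.msd_mm <= pooled_surface_distances(a, b).max()
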