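"""Otsu thresholding, seeded region growing, and mask union."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from cowlabel import (
    BinaryMask,
    DegenerateInputError,
    InputError,
    IntensityVolume,
    SeedPoint,
    make_tube_volume,
    otsu_threshold,
    region_grow_3d,
    union_masks,
)
from cowlabel.phantom import PhantomSpec, VesselCurve


def _tube_volume(noise_sd=0.0, seed=0):
    spec = PhantomSpec(
        shape=(32, 16, 16),
        vessels=(VesselCurve("BA", ((4.0, 8.0, 8.0), (28.0, 8.0, 8.0)), radius=2.0,
                             intensity=300.0),),
        background=50.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return make_tube_volume(spec)


def _flood_oracle(static_ok: np.ndarray, seed, connectivity: int) -> np.ndarray:
    """Connected component of the static acceptance set containing the seed."""
    structure = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, _ = ndimage.label(static_ok, structure=structure)
    return labels == labels[seed]


class TestOtsu:
    def test_bimodal_threshold_separates_classes(self):
        data = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        vol = IntensityVolume(data=data.reshape(10, 10, 10), spacing=(1, 1, 1))
        t = otsu_threshold(vol)
        assert 10.0 < t < 200.0

    def test_constant_volume_is_degenerate(self):
        vol = IntensityVolume(data=np.full((4, 4, 4), 7.0), spacing=(1, 1, 1))
        with pytest.raises(DegenerateInputError):
            otsu_threshold(vol)

    def test_threshold_maximizes_between_class_variance(self):
        # exhaustive search over histogram cut points is the oracle
        rng = np.random.default_rng(3)
        data = np.concatenate(
            [rng.normal(60, 8, 600), rng.normal(250, 15, 400)]
        ).reshape(10, 10, 10)
        vol = IntensityVolume(data=data, spacing=(1, 1, 1))
        n_bins = 64
        t = otsu_threshold(vol, n_bins=n_bins)
        hist, edges = np.histogram(data, bins=n_bins)
        centers = (edges[:-1] + edges[1:]) / 2

        def between_class_variance(k):
            w0, w1 = hist[:k].sum(), hist[k:].sum()
            if w0 == 0 or w1 == 0:
                return -1.0
            m0 = (hist[:k] * centers[:k]).sum() / w0
            m1 = (hist[k:] * centers[k:]).sum() / w1
            return w0 * w1 * (m0 - m1) ** 2

        best_var = max(between_class_variance(k) for k in range(1, n_bins))
        # the returned threshold is a bin center; splitting there must
        # achieve the maximal between-class variance (ties are a plateau
        # of empty bins between the modes, all equally optimal)
        k_t = int(np.argmin(np.abs(centers - t))) + 1
        assert between_class_variance(k_t) == pytest.approx(best_var, rel=1e-9)

    def test_noisy_tube_recovered_by_thresholding(self):
        vol, _, masks = _tube_volume(noise_sd=10.0, seed=1)
        t = otsu_threshold(vol)
        recovered = vol.data >= t
        truth = masks["BA"].data
        assert (recovered & truth).sum() / truth.sum() >= 0.99


class TestRegionGrow:
    def test_uniform_tube_grown_exactly(self):
        vol, _, masks = _tube_volume(noise_sd=0.0)
        seed = SeedPoint(coordinate=(16, 8, 8), label="BA")
        grown = region_grow_3d(vol, seed, max_deviation=100.0)
        oracle = _flood_oracle(np.abs(vol.data - 300.0) <= 100.0, seed.coordinate, 6)
        np.testing.assert_array_equal(grown.data, oracle)
        np.testing.assert_array_equal(grown.data, masks["BA"].data)

    def test_background_seed_never_reaches_tube(self):
        vol, _, masks = _tube_volume(noise_sd=0.0)
        seed = SeedPoint(coordinate=(2, 2, 2), label="bg")
        grown = region_grow_3d(vol, seed, max_deviation=100.0)
        assert not (grown.data & masks["BA"].data).any()
        oracle = _flood_oracle(np.abs(vol.data - 50.0) <= 100.0, seed.coordinate, 6)
        np.testing.assert_array_equal(grown.data, oracle)

    def test_zero_tolerance_accepts_only_exact_matches(self):
        rng = np.random.default_rng(5)
        vol = IntensityVolume(data=rng.normal(100, 30, (8, 8, 8)), spacing=(1, 1, 1))
        grown = region_grow_3d(vol, SeedPoint(coordinate=(4, 4, 4)), max_deviation=0.0)
        assert grown.data[4, 4, 4]
        # continuous noise: almost surely only the seed matches its own mean
        assert grown.count() == 1

    def test_connectivity_26_reaches_diagonal_gap(self):
        data = np.full((3, 3, 3), 0.0)
        data[0, 0, 0] = data[1, 1, 1] = 200.0
        vol = IntensityVolume(data=data, spacing=(1, 1, 1))
        seed = SeedPoint(coordinate=(0, 0, 0))
        assert region_grow_3d(vol, seed, 10.0, connectivity=6).count() == 1
        assert region_grow_3d(vol, seed, 10.0, connectivity=26).count() == 2

    def test_tolerance_monotonicity(self):
        vol, _, _ = _tube_volume(noise_sd=10.0, seed=2)
        seed = SeedPoint(coordinate=(16, 8, 8))
        small = region_grow_3d(vol, seed, max_deviation=30.0)
        large = region_grow_3d(vol, seed, max_deviation=120.0)
        assert (small.data <= large.data).all()

    def test_seed_outside_grid_rejected(self):
        vol, _, _ = _tube_volume()
        with pytest.raises(InputError, match="outside"):
            region_grow_3d(vol, SeedPoint(coordinate=(99, 0, 0)), 10.0)

    def test_negative_tolerance_rejected(self):
        vol, _, _ = _tube_volume()
        with pytest.raises(InputError, match="max_deviation"):
            region_grow_3d(vol, SeedPoint(coordinate=(16, 8, 8)), -1.0)


masks_3x3 = st.builds(
    lambda bits: BinaryMask(
        data=np.array(bits, dtype=bool).reshape(3, 3, 3), spacing=(1.0, 1.0, 1.0)
    ),
    st.lists(st.booleans(), min_size=27, max_size=27),
)


class TestUnionMasks:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=masks_3x3, b=masks_3x3, c=masks_3x3)
    def test_commutative_associative_idempotent(self, a, b, c):
        ab = union_masks([a, b]).data
        ba = union_masks([b, a]).data
        np.testing.assert_array_equal(ab, ba)
        abc1 = union_masks([union_masks([a, b]), c]).data
        abc2 = union_masks([a, union_masks([b, c])]).data
        np.testing.assert_array_equal(abc1, abc2)
        np.testing.assert_array_equal(union_masks([a, a]).data, a.data)

    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(0)
        a = BinaryMask(data=rng.random((4, 4, 4)) > 0.5, spacing=(1, 1, 1))
        empty = BinaryMask(data=np.zeros((4, 4, 4), bool), spacing=(1, 1, 1))
        np.testing.assert_array_equal(union_masks([a, empty]).data, a.data)

    def test_disjoint_masks_add(self, phantom_missing_pcomms):
        masks = [phantom_missing_pcomms.vessel_masks[n] for n in ("R-P2", "L-P2", "AComm")]
        total = union_masks(masks).count()
        assert total == sum(m.count() for m in masks)

    def test_shape_mismatch_rejected(self):
        a = BinaryMask(data=np.zeros((3, 3, 3), bool), spacing=(1, 1, 1))
        b = BinaryMask(data=np.zeros((4, 3, 3), bool), spacing=(1, 1, 1))
        with pytest.raises(InputError, match="shape"):
            union_masks([a, b])
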