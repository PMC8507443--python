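import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelviseg import BinaryMask, CTVolume, ParameterError, PipelineParams, \
    combine_masks, local_maximum_mask, region_grow, threshold_segment

from conftest import bfs_region_grow_oracle, box_mean_oracle


class TestPipelineParams:
    def test_seed_threshold_must_exceed_bone_threshold(self):
        with pytest.raises(ParameterError, match="t_seed"):
            PipelineParams(t_bone=200, t_seed=100)

    def test_box_n_must_be_odd(self):
        with pytest.raises(ParameterError, match="box_n"):
            PipelineParams(box_n=8)

    def test_acceptance_range_ordering(self):
        with pytest.raises(ParameterError, match="accept_low"):
            PipelineParams(accept_low=500, accept_high=100)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ParameterError, match="unknown"):
            PipelineParams.from_dict({"t_bne": 300})

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        p = PipelineParams(t_bone=250, t_seed=500, box_n=5)
        path = tmp_path / "cfg.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(p.to_dict(), fh)
        assert PipelineParams.from_yaml(path) == p


class TestThresholdSegment:
    def test_dual_threshold_selects_expected_voxels(self):
        vol = CTVolume(np.array([100.0, 200.0, 300.0]).reshape(3, 1, 1))
        params = PipelineParams(t_bone=150, t_seed=250)
        bone, seed = threshold_segment(vol, params)
        assert bone.data.ravel().tolist() == [False, True, True]
        assert seed.data.ravel().tolist() == [False, False, True]

    def test_all_below_threshold_gives_empty_masks(self):
        vol = CTVolume(np.zeros((4, 4, 4)))
        bone, seed = threshold_segment(vol, PipelineParams())
        assert not bone.data.any() and not seed.data.any()

    def test_matches_elementwise_oracle_and_seed_subset(self, small_volume):
        params = PipelineParams(t_bone=300, t_seed=700)
        bone, seed = threshold_segment(small_volume, params)
        np.testing.assert_array_equal(bone.data, small_volume.data >= 300)
        np.testing.assert_array_equal(seed.data, small_volume.data >= 700)
        assert np.all(bone.data[seed.data])


class TestLocalMaximumMask:
    def test_constant_volume_gives_empty_mask(self):
        vol = CTVolume(np.full((10, 10, 10), 77.0))
        assert not local_maximum_mask(vol, 3).data.any()

    def test_single_spike_closed_form(self):
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 1000.0
        mask = local_maximum_mask(CTVolume(data), 3)
        assert mask.data[3, 3, 3]  # 1000 > 1000/27
        assert mask.data.sum() == 1  # zero voxels never beat a mean >= 0

    def test_even_box_rejected(self):
        with pytest.raises(ParameterError):
            local_maximum_mask(CTVolume(np.zeros((5, 5, 5))), 4)

    @pytest.mark.parametrize("box_n", [3, 5, 9])
    def test_matches_explicit_summation_oracle(self, box_n, rng):
        data = rng.integers(-500, 1500, size=(15, 15, 15)).astype(float)
        vol = CTVolume(data)
        mask = local_maximum_mask(vol, box_n)
        np.testing.assert_array_equal(mask.data, data > box_mean_oracle(data, box_n))

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), shift=st.integers(-2000, 2000))
    def test_invariant_under_intensity_shift(self, seed, shift):
        r = np.random.default_rng(seed)
        data = r.integers(-100, 100, size=(9, 9, 9)).astype(float)
        m1 = local_maximum_mask(CTVolume(data), 5)
        m2 = local_maximum_mask(CTVolume(data + shift), 5)
        np.testing.assert_array_equal(m1.data, m2.data)


def _random_grow_instance(r, shape=(12, 12, 12)):
    vol = CTVolume(r.integers(0, 1000, size=shape).astype(float))
    lmax = BinaryMask(r.random(shape) < 0.55)
    seeds = BinaryMask(r.random(shape) < 0.03)
    params = PipelineParams(t_bone=200, t_seed=400, accept_low=250, accept_high=750)
    return vol, seeds, lmax, params


class TestRegionGrow:
    def test_fully_admissible_block_grows_completely(self):
        vol = CTVolume(np.full((3, 3, 3), 500.0))
        lmax = BinaryMask(np.ones((3, 3, 3), dtype=bool))
        seeds = BinaryMask(np.zeros((3, 3, 3), dtype=bool))
        seeds.data[1, 1, 1] = True
        params = PipelineParams(t_bone=200, t_seed=400, accept_low=100)
        grown = region_grow(vol, seeds, lmax, params)
        assert grown.data.all()

    def test_no_growth_when_neighbours_fail_acceptance(self):
        vol = CTVolume(np.zeros((3, 3, 3)))
        vol.data[1, 1, 1] = 500.0
        lmax = BinaryMask(np.ones((3, 3, 3), dtype=bool))
        seeds = BinaryMask(vol.data > 400)
        params = PipelineParams(t_bone=200, t_seed=400, accept_low=100)
        grown = region_grow(vol, seeds, lmax, params)
        np.testing.assert_array_equal(grown.data, seeds.data)

    def test_empty_seed_mask_warns_and_returns_empty(self, small_volume):
        empty = BinaryMask.like(small_volume, np.zeros(small_volume.shape, dtype=bool))
        with pytest.warns(UserWarning, match="empty seed"):
            grown = region_grow(small_volume, empty, empty, PipelineParams())
        assert not grown.data.any()

    def test_matches_bfs_oracle_on_random_instances(self, rng):
        for _ in range(10):
            vol, seeds, lmax, params = _random_grow_instance(rng)
            grown = region_grow(vol, seeds, lmax, params)
            admissible = (lmax.data & (vol.data >= params.accept_low)
                          & (vol.data <= params.accept_high)) | seeds.data
            expected = bfs_region_grow_oracle(admissible, seeds.data)
            np.testing.assert_array_equal(grown.data, expected)

    def test_result_invariant_under_seed_splitting(self, rng):
        vol, seeds, lmax, params = _random_grow_instance(rng)
        full = region_grow(vol, seeds, lmax, params)
        half = np.zeros(vol.shape, dtype=bool)
        half[:6] = True
        part_a = BinaryMask(seeds.data & half)
        part_b = BinaryMask(seeds.data & ~half)
        union = np.zeros(vol.shape, dtype=bool)
        for part in (part_a, part_b):
            if part.data.any():
                union |= region_grow(vol, part, lmax, params).data
        np.testing.assert_array_equal(full.data, union)

    def test_sandwiched_between_seeds_and_admissible_set(self, rng):
        vol, seeds, lmax, params = _random_grow_instance(rng)
        grown = region_grow(vol, seeds, lmax, params)
        assert np.all(grown.data[seeds.data])
        admissible = (lmax.data & (vol.data >= params.accept_low)
                      & (vol.data <= params.accept_high)) | seeds.data
        assert np.all(admissible[grown.data])


class TestCombineMasks:
    def test_union_is_idempotent_commutative_and_extensive(self, rng):
        a = BinaryMask(rng.random((8, 8, 8)) < 0.3)
        b = BinaryMask(rng.random((8, 8, 8)) < 0.3)
        ab = combine_masks(a, b)
        np.testing.assert_array_equal(ab.data, a.data | b.data)
        np.testing.assert_array_equal(ab.data, combine_masks(b, a).data)
        assert np.all(ab.data[a.data]) and np.all(ab.data[b.data])
        np.testing.assert_array_equal(combine_masks(a, a).data, a.data)

    def test_disjoint_masks_add_cardinalities(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        b = np.zeros((5, 5, 5), dtype=bool)
        a.ravel()[:10] = True
        b.ravel()[20:40] = True
        out = combine_masks(BinaryMask(a), BinaryMask(b))
        assert out.data.sum() == 30

    def test_shape_mismatch_raises(self):
        from pelviseg import AlignmentError
        with pytest.raises(AlignmentError):
            combine_masks(BinaryMask(np.zeros((4, 4, 4), dtype=bool)),
                          BinaryMask(np.zeros((4, 4, 5), dtype=bool)))
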