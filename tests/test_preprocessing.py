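import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pelviseg import CTVolume, EmptyBodyError, ParameterError, ReferenceHistogram, \
    match_histogram, remove_table


def _body_cdf(values, grid):
    values = np.sort(values)
    return np.searchsorted(values, grid, side="right") / values.size


class TestReferenceHistogram:
    def test_invariants_enforced(self):
        with pytest.raises(ParameterError):
            ReferenceHistogram(bin_edges=[0, 0, 1], cdf=[0, 0.5, 1.0])  # non-increasing edges
        with pytest.raises(ParameterError):
            ReferenceHistogram(bin_edges=[0, 1, 2], cdf=[0, 0.9, 0.95])  # last != 1
        with pytest.raises(ParameterError):
            ReferenceHistogram(bin_edges=[0, 1, 2], cdf=[0.5, 0.2, 1.0])  # decreasing

    def test_file_round_trip(self, tmp_path, small_volume):
        ref = ReferenceHistogram.from_volume(small_volume, source_id="rt")
        path = tmp_path / "ref.csv"
        ref.to_file(path)
        back = ReferenceHistogram.from_file(path)
        np.testing.assert_allclose(back.bin_edges, ref.bin_edges)
        np.testing.assert_allclose(back.cdf, ref.cdf, atol=1e-7)


class TestMatchHistogram:
    def test_self_matching_changes_at_most_one_bin(self, small_volume):
        ref = ReferenceHistogram.from_volume(small_volume)
        out = match_histogram(small_volume, ref)
        body = small_volume.data > -500
        assert np.max(np.abs(out.data[body] - small_volume.data[body])) <= 1.0

    def test_shifted_volume_recovers_reference_distribution(self, rng):
        # bimodal body distribution, then a +100 HU global shift
        base = np.concatenate([rng.normal(40, 30, 6000), rng.normal(1000, 150, 1500)])
        vol = CTVolume(np.clip(base, -400, 2800).reshape(15, 20, 25))
        shifted = vol.with_data(vol.data + 100.0)
        ref = ReferenceHistogram.from_volume(vol)
        out = match_histogram(shifted, ref)
        grid = np.arange(-1024.0, 3072.0)
        ks = np.max(np.abs(_body_cdf(out.data[out.data > -500], grid)
                           - _body_cdf(vol.data[vol.data > -500], grid)))
        assert ks < 0.05

    def test_constant_volume_maps_to_reference_median(self, small_volume):
        ref = ReferenceHistogram.from_volume(small_volume)
        const = small_volume.with_data(np.zeros_like(small_volume.data))
        with pytest.warns(UserWarning, match="degenerate"):
            out = match_histogram(const, ref)
        expected = np.interp(0.5, ref.cdf, ref.bin_edges)
        np.testing.assert_allclose(out.data, expected, atol=1e-4)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-300, 300),
           scale=st.floats(0.5, 2.0))
    def test_mapping_is_monotone(self, seed, shift, scale):
        r = np.random.default_rng(seed)
        vol = CTVolume(r.normal(200, 300, size=(8, 8, 8)).clip(-1000, 3000))
        ref_vol = CTVolume((r.normal(100, 200, size=(8, 8, 8)) * scale + shift)
                           .clip(-1000, 3000))
        ref = ReferenceHistogram.from_volume(ref_vol)
        out = match_histogram(vol, ref)
        order = np.argsort(vol.data.ravel(), kind="stable")
        mapped_sorted = out.data.ravel()[order]
        assert np.all(np.diff(mapped_sorted) >= -1e-3)

    def test_idempotent_up_to_one_bin(self, small_volume):
        ref = ReferenceHistogram.from_volume(small_volume)
        once = match_histogram(small_volume, ref)
        twice = match_histogram(once, ref)
        assert np.max(np.abs(twice.data - once.data)) <= 1.0


class TestRemoveTable:
    @staticmethod
    def _body_and_table(table_hu=-300.0):
        data = np.full((40, 40, 20), -1000.0)
        idx = np.indices(data.shape)
        body = ((idx[0] - 20) ** 2 / 15 ** 2 + (idx[1] - 15) ** 2 / 10 ** 2
                + (idx[2] - 10) ** 2 / 8 ** 2) <= 1
        data[body] = 0.0
        table = np.zeros(data.shape, dtype=bool)
        table[5:35, 32:36, :] = True
        data[table] = table_hu
        return CTVolume(data), body, table

    def test_disjoint_table_removed_body_kept(self):
        vol, body, table = self._body_and_table()
        cleaned, mask = remove_table(vol, air_threshold=-500)
        assert np.all(cleaned.data[table] == -1000.0)
        np.testing.assert_array_equal(cleaned.data[body], vol.data[body])
        assert np.all(mask.data[body])

    def test_single_component_untouched(self):
        vol, body, _ = self._body_and_table(table_hu=-900.0)  # table below threshold
        cleaned, mask = remove_table(vol, air_threshold=-500)
        np.testing.assert_array_equal(cleaned.data[body], vol.data[body])
        assert mask.data.sum() >= body.sum()

    def test_all_air_raises_empty_body(self):
        vol = CTVolume(np.full((10, 10, 10), -1000.0))
        with pytest.raises(EmptyBodyError, match="empty body"):
            remove_table(vol, air_threshold=-500)

    def test_largest_component_never_shrinks(self, rng):
        from scipy import ndimage
        data = np.where(rng.random((20, 20, 20)) < 0.3, 100.0, -1000.0)
        vol = CTVolume(data)
        above = data > -500
        labels, n = ndimage.label(above, structure=np.ones((3, 3, 3)))
        largest = labels == (np.argmax(ndimage.sum_labels(above, labels,
                                                          np.arange(1, n + 1))) + 1)
        _, mask = remove_table(vol, air_threshold=-500)
        assert np.all(mask.data[largest])
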