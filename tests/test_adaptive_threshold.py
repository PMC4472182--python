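import numpy as np
import pytest

from fcvessel import (
    ConnectivityScene,
    apply_threshold,
    find_peaks,
    histogram,
    suggest_threshold,
    volume_above,
)
from fcvessel.adaptive_threshold import ConnectivityHistogram


def make_cs(values, spacing=(1.0, 1.0, 1.0), seed=(0, 0, 0)):
    return ConnectivityScene(np.asarray(values, dtype=np.float64), spacing, seed)


def make_hist(counts, voxel_volume_ml=0.001):
    counts = np.asarray(counts, dtype=np.int64)
    edges = np.linspace(0.0, 1.0, len(counts) + 1)
    return ConnectivityHistogram(edges, counts, voxel_volume_ml)


class TestHistogram:
    def test_seed_only_scene_fills_last_bin(self):
        cs_values = np.zeros((4, 4, 4))
        cs_values[0, 0, 0] = 1.0
        h = histogram(make_cs(cs_values), bins=10)
        assert h.counts.tolist() == [0] * 9 + [1]

    def test_uniform_unit_connectivity(self):
        h = histogram(make_cs(np.ones((3, 3, 3))), bins=10)
        assert h.counts[-1] == 27

    def test_counts_conserve_positive_voxels(self):
        rng = np.random.default_rng(0)
        values = rng.random((6, 6, 6))
        values[values < 0.3] = 0.0
        h = histogram(make_cs(values), bins=50)
        assert h.counts.sum() == (values > 0).sum()

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            histogram(make_cs(np.ones((2, 2, 2))), bins=1)


class TestVolumeAbove:
    def test_portal_vein_scale_example(self):
        # 24,904 voxels at 0.671 x 0.671 x 1 mm in the top bins
        counts = np.zeros(1000, dtype=np.int64)
        counts[-2:] = [12452, 12452]
        h = ConnectivityHistogram(np.linspace(0, 1, 1001), counts, 0.671 * 0.671 * 1.0 / 1000)
        assert volume_above(0.99, h) == pytest.approx(11.213, abs=5e-4)

    def test_at_one_counts_last_bin_only(self):
        h = make_hist([5, 0, 0, 7])
        assert volume_above(1.0, h) == pytest.approx(7 * h.voxel_volume_ml)

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            h = make_hist(rng.integers(0, 50, rng.integers(2, 40)))
            hs = np.sort(rng.random(10))
            vols = [volume_above(x, h) for x in hs]
            assert all(a >= b for a, b in zip(vols, vols[1:]))


class TestFindPeaks:
    def test_simple_interior_peak(self):
        assert find_peaks(make_hist([1, 5, 1]), smooth_window=1) == [1]

    def test_strictly_increasing_counts_peak_at_last_bin(self):
        assert find_peaks(make_hist([1, 2, 3, 4]), smooth_window=1) == [3]

    def test_plateau_resolves_to_left_edge(self):
        assert find_peaks(make_hist([1, 5, 5, 1]), smooth_window=1) == [1]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            find_peaks(make_hist([1, 2, 1]), smooth_window=4)


class TestSuggestThreshold:
    def test_background_mass_then_vessel_peak(self):
        """Hand-traced bimodal case: a large low-connectivity mass whose
        volume exceeds the cap, a long empty valley, and a compact vessel
        peak near 0.9.  EP lands inside the background tail (where the
        cumulative volume first stays under 50 ml) and the search must
        walk to the vessel peak."""
        counts = np.zeros(100, dtype=np.int64)
        counts[1:11] = [40000, 20000, 10000, 5000, 3000, 2000, 1000, 500, 300, 200]
        counts[90:93] = [3000, 4000, 1000]  # vessel peak at bin 91
        h = make_hist(counts, voxel_volume_ml=0.001)  # 1 mm^3 voxels
        # cumulative volume from above: vessel mass = 8 ml < 50 ml, so EP
        # sits where the background tail pushes the cumulative over 50 ml
        res = suggest_threshold(h, max_volume_ml=50.0, smooth_window=1)
        assert res.EP < 0.11
        assert not res.ep_is_peak
        assert res.T == pytest.approx(0.91)  # left edge of the peak bin
        assert res.volume_at_T_ml == pytest.approx(5.0)

    def test_total_volume_below_cap_falls_back_to_lowest_edge(self):
        h = make_hist([0, 3, 1, 0, 2], voxel_volume_ml=0.001)
        res = suggest_threshold(h, max_volume_ml=50.0, smooth_window=1)
        assert res.EP == pytest.approx(0.2)

    def test_single_top_bin_is_its_own_peak(self):
        counts = np.zeros(10, dtype=np.int64)
        counts[-1] = 100000
        res = suggest_threshold(make_hist(counts), max_volume_ml=50.0, smooth_window=1)
        assert res.EP == 1.0 and res.T == 1.0 and res.ep_is_peak

    def test_threshold_never_below_endpoint(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            h = make_hist(rng.integers(0, 1000, 50), voxel_volume_ml=0.001)
            if h.counts.sum() == 0:
                continue
            res = suggest_threshold(h, max_volume_ml=rng.uniform(0.01, 10))
            assert res.T >= res.EP

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            suggest_threshold(make_hist([0, 0, 0]))


class TestApplyThreshold:
    def test_unit_threshold_keeps_unique_maximum_seed(self):
        values = np.zeros((3, 3, 3))
        values[1, 1, 1] = 1.0
        values[0, 0, 0] = 0.99
        mask = apply_threshold(make_cs(values, seed=(1, 1, 1)), 1.0)
        assert mask.voxel_count == 1 and mask.values[1, 1, 1]

    def test_mask_size_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        cs = make_cs(rng.random((5, 5, 5)))
        sizes = [apply_threshold(cs, t).voxel_count for t in (0.1, 0.4, 0.7, 0.95)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_seed_always_included(self):
        cs = make_cs(np.zeros((3, 3, 3)), seed=(2, 2, 2))
        assert apply_threshold(cs, 0.5).values[2, 2, 2]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError, match="threshold"):
            apply_threshold(make_cs(np.ones((2, 2, 2))), bad)
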