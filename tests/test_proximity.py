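import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibertension as ft
from fibertension.io_core import BinaryMask
from fibertension.cellquant import CellRecord, CellTable


def brute_force_distance(mask_values, pixel_size):
    """O(N*M) nearest-true-pixel distance for every pixel."""
    ys, xs = np.nonzero(mask_values)
    out = np.empty(mask_values.shape)
    for r in range(mask_values.shape[0]):
        for c in range(mask_values.shape[1]):
            out[r, c] = np.sqrt(((ys - r) ** 2 + (xs - c) ** 2).min())
    return out * pixel_size


def table_at(centroids_um, pixel_size=0.5):
    cells = [CellRecord(i + 1, tuple(xy), 25.0) for i, xy in enumerate(centroids_um)]
    return CellTable(cells=cells, pixel_size=pixel_size)


class TestDistanceMap:
    def test_three_four_five_triangle(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2, 3] = True
        dmap = ft.distance_map(BinaryMask(mask), pixel_size=0.5)
        assert dmap.values[5, 7] == pytest.approx(2.5)  # 3 rows + 4 cols away

    def test_all_true_mask_is_zero(self):
        dmap = ft.distance_map(BinaryMask(np.ones((8, 8), bool)), 1.0)
        assert np.all(dmap.values == 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no target pixels"):
            ft.distance_map(BinaryMask(np.zeros((8, 8), bool)), 1.0)

    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(0)
        mask = rng.random((32, 32)) > 0.95
        mask[0, 0] = True
        dmap = ft.distance_map(BinaryMask(mask), 0.5)
        np.testing.assert_allclose(dmap.values, brute_force_distance(mask, 0.5), atol=1e-9)

    def test_shrinking_mask_never_decreases_distances(self):
        rng = np.random.default_rng(1)
        big = rng.random((24, 24)) > 0.8
        big[3, 3] = True
        small = big.copy()
        keep = rng.random((24, 24)) > 0.5
        small &= keep
        small[3, 3] = True
        d_big = ft.distance_map(BinaryMask(big), 1.0).values
        d_small = ft.distance_map(BinaryMask(small), 1.0).values
        assert np.all(d_small >= d_big - 1e-12)


class TestCellDistances:
    def test_centroid_on_positive_pixel_is_zero(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[4, 4] = True
        # centroid at the center of pixel (4, 4): x = y = 2.25 um at 0.5 um/px
        d = ft.cell_nearest_distances(table_at([(2.25, 2.25)]), BinaryMask(mask), 0.5)
        assert d[0] == 0.0

    def test_single_pixel_345_geometry(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[2, 3] = True
        d = ft.cell_nearest_distances(table_at([(3.75, 2.75)]), BinaryMask(mask), 0.5)
        assert d[0] == pytest.approx(2.5)

    def test_distances_match_generator_truth(self, invasive_sample, analyzed10, config):
        truth = invasive_sample.truth
        mask = truth.true_masks["FnBPA5"]
        d = ft.cell_nearest_distances(
            table_at(truth.cells[["x_um", "y_um"]].values.tolist()), mask, config.pixel_size)
        # centroid discretization allows at most one pixel of slack
        np.testing.assert_allclose(d, truth.cells["dist_fnbpa5_um"].values,
                                   atol=config.pixel_size)


class TestProfile:
    def test_bin_arithmetic(self):
        prof = ft.proximity_profile(np.array([0.5, 0.5, 1.5, 25.0]))
        assert prof.fraction_per_bin[0] == pytest.approx(50.0)
        assert prof.fraction_per_bin[1] == pytest.approx(25.0)
        assert prof.overflow_fraction == pytest.approx(25.0)
        assert prof.n_cells == 4

    def test_all_beyond_max_is_pure_overflow(self):
        prof = ft.proximity_profile(np.full(7, 99.0))
        assert prof.overflow_fraction == pytest.approx(100.0)
        assert prof.fraction_per_bin.sum() == 0.0

    def test_zero_flagged_cells_flagged(self):
        prof = ft.proximity_profile(np.array([1.0, 2.0]), flags=np.array([False, False]))
        assert prof.n_cells == 0
        assert np.isnan(prof.overflow_fraction)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fractions_sum_to_100(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.exponential(6.0, size=rng.integers(1, 200))
        prof = ft.proximity_profile(d)
        assert prof.fraction_per_bin.sum() + prof.overflow_fraction == pytest.approx(100.0,
                                                                                     abs=1e-9)

    def test_exponential_law_bins_match_closed_form(self):
        # coupled-placement contract: binned fractions follow the exponential CDF
        rng = np.random.default_rng(0)
        scale, n = 4.0, 500
        d = rng.exponential(scale, n)
        prof = ft.proximity_profile(d)
        for k in range(20):
            p = np.exp(-k / scale) - np.exp(-(k + 1) / scale)
            sigma = np.sqrt(p * (1 - p) / n)
            assert abs(prof.fraction_per_bin[k] / 100.0 - p) <= 3 * sigma + 1e-12


class TestFractionWithin:
    def test_inclusive_boundary(self):
        assert ft.fraction_within(np.array([0.0, 5.0, 10.0, 15.0])) == pytest.approx(75.0)

    def test_all_beyond_radius(self):
        assert ft.fraction_within(np.array([11.0, 30.0])) == 0.0

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(2)
        d = rng.exponential(5.0, 200)
        fracs = [ft.fraction_within(d, radius=r) for r in (2.0, 5.0, 10.0, 20.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_no_flagged_cells_rejected(self):
        with pytest.raises(ValueError):
            ft.fraction_within(np.array([1.0]), flags=np.array([False]))


class TestTwoStage:
    def _masks(self):
        a = np.zeros((64, 64), dtype=bool)
        a[10, 10] = True
        b = np.zeros((64, 64), dtype=bool)
        b[10, 58] = True
        return BinaryMask(a), BinaryMask(b)

    def test_single_cell_mean(self):
        mask_a, mask_b = self._masks()
        # cell on pixel (10, 20): 5 um from A, 19 um from B at 0.5 um/px
        table = table_at([(10.25, 5.25)])
        mean_d, dists = ft.two_stage_proximity(table, mask_a, mask_b, 0.5)
        assert dists.size == 1
        assert mean_d == pytest.approx(19.0)

    def test_no_cell_within_radius_is_flagged_empty(self):
        mask_a, mask_b = self._masks()
        table = table_at([(30.25, 30.25)])  # far from A
        mean_d, dists = ft.two_stage_proximity(table, mask_a, mask_b, 0.5)
        assert dists.size == 0 and np.isnan(mean_d)

    def test_cafs_farther_from_vessels_in_invasive_tissue(self, analyzed10):
        # myofibroblast-like cells near untensed fibers sit close to vessels
        # in healthy tissue (smooth muscle) but far from them in tumors (CAFs)
        for rh, ri in zip(analyzed10["healthy"], analyzed10["invasive_G2"]):
            assert rh["two_stage"]["n_selected"] > 0
            assert ri["two_stage"]["n_selected"] > 0
            assert ri["two_stage"]["mean_distance_um"] > rh["two_stage"]["mean_distance_um"]
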