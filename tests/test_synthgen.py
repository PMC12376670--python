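import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import fibertension as ft
from fibertension.synthgen import PRESETS, synth_cells, synth_fibers

SMALL = (256, 256)
PX = 0.5


class TestPresets:
    def test_untensed_fraction_ordering_of_defaults(self):
        assert (PRESETS["healthy"].fnbpa5_fraction
                < PRESETS["invasive_G2"].fnbpa5_fraction
                < PRESETS["invasive_G3"].fnbpa5_fraction)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            replace(PRESETS["healthy"], cell_mix={"stromal": 0.5})


class TestSynthFibers:
    def test_healthy_fraction_hits_target(self, healthy_sample):
        assert abs(healthy_sample.truth.fnbpa5_fraction - 0.08) <= 0.02

    def test_invasive_fraction_hits_target(self, invasive_sample):
        assert abs(invasive_sample.truth.fnbpa5_fraction - 0.35) <= 0.03

    def test_degenerate_alignment_gives_zero_circular_variance(self):
        preset = replace(PRESETS["invasive_G2"], fiber_alignment=float("inf"),
                         fiber_waviness=(0.0, 60.0))
        _, truth = synth_fibers(preset, SMALL, seed=0, pixel_size=PX)
        angles = truth.fiber_orientation[np.isfinite(truth.fiber_orientation)]
        doubled = np.deg2rad(2 * angles)
        resultant = np.hypot(np.cos(doubled).mean(), np.sin(doubled).mean())
        assert 1.0 - resultant == pytest.approx(0.0, abs=1e-12)

    def test_tiny_frame_rejected(self):
        with pytest.raises(ValueError):
            synth_fibers(PRESETS["healthy"], (32, 32), seed=0)

    def test_tnc_halo_contains_fnbpa5(self):
        _, truth = synth_fibers(PRESETS["invasive_G2"], SMALL, seed=1, pixel_size=PX)
        fn = truth.true_masks["FnBPA5"].values
        tnc = truth.true_masks["TNC"].values
        assert np.all(tnc[fn])


class TestSynthCells:
    def test_coupled_cells_follow_exponential_law(self):
        preset = replace(PRESETS["invasive_G2"], proximity_scale=3.0)
        rng = np.random.default_rng(0)
        _, ftruth = synth_fibers(preset, (1024, 1024), rng, PX)
        _, ctruth = synth_cells(preset, ftruth, (1024, 1024), rng, PX,
                                n_cells=500, cell_mix={"cancer": 1.0})
        within = (ctruth.cells["dist_fnbpa5_um"] <= 10.0).mean()
        assert within >= 0.90  # closed form: 1 - exp(-10/3) ~ 0.964

    def test_empty_class_yields_no_cells(self):
        rng = np.random.default_rng(0)
        preset = PRESETS["invasive_G2"]
        _, ftruth = synth_fibers(preset, SMALL, rng, PX)
        _, ctruth = synth_cells(preset, ftruth, SMALL, rng, PX, n_cells=30,
                                cell_mix={"cancer": 0.0, "stromal": 1.0})
        assert (ctruth.cells["phenotype"] == "cancer").sum() == 0

    def test_same_seed_reproduces_cell_truth(self):
        preset = PRESETS["invasive_G2"]
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            _, ftruth = synth_fibers(preset, SMALL, rng, PX)
            _, ctruth = synth_cells(preset, ftruth, SMALL, rng, PX)
            outs.append(ctruth.cells)
        pd.testing.assert_frame_equal(outs[0], outs[1])

    def test_nuclei_do_not_overlap(self):
        s = ft.generate_tissue("invasive_G3", SMALL, PX, seed=5)
        cells = s.truth.cells
        xy = cells[["x_um", "y_um"]].values
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        min_sep = np.sqrt(d2.min())
        # centers at least one mean nucleus radius apart
        assert min_sep >= s.preset.nucleus_radius_mean


class TestGenerateTissue:
    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            ft.generate_tissue("nope", SMALL, PX, seed=0)

    def test_healthy_tnc_sparser_than_invasive(self):
        h = ft.generate_tissue("healthy", SMALL, PX, seed=1)
        i = ft.generate_tissue("invasive_G2", SMALL, PX, seed=1)
        assert h.truth.density("TNC") < i.truth.density("TNC")

    def test_high_grade_richer_in_untensed_fibers(self):
        g2 = ft.generate_tissue("invasive_G2", SMALL, PX, seed=1)
        g3 = ft.generate_tissue("invasive_G3", SMALL, PX, seed=1)
        assert g3.truth.fnbpa5_fraction > g2.truth.fnbpa5_fraction

    def test_truth_distances_consistent_with_brute_force(self):
        s = ft.generate_tissue("healthy", SMALL, PX, seed=2)
        ys, xs = np.nonzero(s.truth.true_masks["FnBPA5"].values)
        for _, row in s.truth.cells.iterrows():
            r, c = int(row["row"]), int(row["col"])
            bf = np.sqrt(((ys - r) ** 2 + (xs - c) ** 2).min()) * PX
            assert abs(bf - row["dist_fnbpa5_um"]) < 1e-9

    def test_condition_label_set_from_preset(self, healthy_sample):
        assert healthy_sample.image.condition_label == "healthy"

    def test_truth_captured_before_noise(self, healthy_sample):
        truth = healthy_sample.truth
        # truth masks are exact pre-noise booleans: their fraction equals the
        # recorded achieved value, while the rendered channel is continuous
        assert truth.fnbpa5_fraction == pytest.approx(
            truth.meta["fnbpa5_fraction_achieved"], abs=1e-12)
        assert len(np.unique(healthy_sample.image["FN"])) > 10_000


class TestCohort:
    def test_sizes_and_distinct_seeds(self):
        cohort = ft.generate_cohort({"healthy": 2, "invasive_G2": 2}, base_seed=7,
                                    shape=SMALL)
        assert len(cohort) == 4
        assert len({s.seed for s in cohort}) == 4
        assert [s.seed for s in cohort] == [7, 8, 9, 10]

    def test_empty_condition(self):
        assert ft.generate_cohort({"healthy": 0}, base_seed=0, shape=SMALL) == []

    def test_regeneration_is_bit_identical(self):
        a = ft.generate_cohort({"healthy": 1}, base_seed=7, shape=SMALL)[0]
        b = ft.generate_cohort({"healthy": 1}, base_seed=7, shape=SMALL)[0]
        for m in a.image.channels:
            np.testing.assert_array_equal(a.image.channels[m], b.image.channels[m])
        pd.testing.assert_frame_equal(a.truth.cells, b.truth.cells)

    def test_mean_untensed_fraction_orders_with_condition(self, cohort10):
        fractions = {cond: np.mean([s.truth.fnbpa5_fraction for s in samples])
                     for cond, samples in cohort10.items()}
        g3 = [synth_fibers(PRESETS["invasive_G3"], (512, 512), seed=s, pixel_size=PX)[1]
              for s in range(10)]
        g3_mean = np.mean([(t.true_masks["FnBPA5"].positive_count
                            / t.true_masks["FN"].positive_count) for t in g3])
        assert fractions["healthy"] < fractions["invasive_G2"] < g3_mean


class TestWriteSample:
    def test_sample_dir_contents(self, tmp_path):
        s = ft.generate_tissue("healthy", (128, 128), PX, seed=0)
        ft.write_sample(s, tmp_path / "out")
        assert (tmp_path / "out" / "image.ome.tiff").exists()
        assert (tmp_path / "out" / "truth_cells.csv").exists()
        assert (tmp_path / "out" / "truth_meta.json").exists()
        mask = ft.read_mask(tmp_path / "out" / "truth_masks" / "FnBPA5.tiff")
        assert mask.positive_count == s.truth.true_masks["FnBPA5"].positive_count
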