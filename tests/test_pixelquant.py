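import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibertension as ft
from fibertension.io_core import BinaryMask, full_region
from fibertension.pixelquant import OTSU_BINS, ThresholdPolicy


def otsu_variance_curve(values, bins=OTSU_BINS):
    """Independent Otsu oracle: per-candidate between-class variance by an
    explicit O(bins^2) loop, plus the candidate thresholds (bin edges)."""
    lo, hi = values.min(), values.max()
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    var = np.full(bins - 1, -np.inf)
    for k in range(bins - 1):
        w0 = hist[:k + 1].sum()
        w1 = hist[k + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:k + 1] * centers[:k + 1]).sum() / w0
        mu1 = (hist[k + 1:] * centers[k + 1:]).sum() / w1
        var[k] = w0 * w1 * (mu0 - mu1) ** 2
    return var, edges[1:]


def otsu_exhaustive_oracle(values, bins=OTSU_BINS):
    """Smallest candidate threshold maximizing the oracle variance curve."""
    var, thresholds = otsu_variance_curve(values, bins)
    return thresholds[int(np.argmax(var))]


def assert_otsu_maximizes_oracle_variance(threshold, values, bins=OTSU_BINS):
    """The chosen threshold must attain the oracle's maximal between-class
    variance (exact up to floating round-off between the two formulations)."""
    var, thresholds = otsu_variance_curve(values, bins)
    k = int(np.argmin(np.abs(thresholds - threshold)))
    assert np.isclose(thresholds[k], threshold)
    assert var[k] >= var.max() * (1.0 - 1e-9)


class TestOtsu:
    def test_two_level_image_separates_classes(self):
        img = np.full((10, 10), 10.0)
        img[:, 5:] = 200.0
        thr = ft.otsu_threshold(img)
        assert 10.0 < thr < 200.0
        assert np.array_equal(img > thr, img == 200.0)

    def test_constant_region_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            ft.otsu_threshold(np.full((8, 8), 3.0))

    def test_matches_exhaustive_search(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            img = np.concatenate([rng.normal(30, 8, 2048), rng.normal(150, 20, 2048)])
            img = np.clip(img, 0, None).reshape(64, 64)
            assert_otsu_maximizes_oracle_variance(ft.otsu_threshold(img), img.ravel())

    def test_in_region_only(self):
        img = np.zeros((16, 16))
        img[:8] = 100.0
        region = BinaryMask(np.zeros((16, 16), dtype=bool) | (np.arange(16) % 2 == 0))
        thr_region = ft.otsu_threshold(img, region)
        assert 0 < thr_region < 100

    def test_affine_invariance_on_two_level_image(self):
        img = np.full((8, 8), 10.0)
        img[:, 4:] = 200.0
        thr = ft.otsu_threshold(img)
        thr_scaled = ft.otsu_threshold(3.0 * img + 7.0)
        # the class split survives any positive affine rescale
        assert np.array_equal(img > thr, (3.0 * img + 7.0) > thr_scaled)


class TestPixelClassifier:
    def test_reproduces_thresholding_rule(self):
        # bimodal intensities, as in stained tissue: background vs signal
        rng = np.random.default_rng(0)
        patches = []
        for _ in range(3):
            p = np.where(rng.random((32, 32)) > 0.5,
                         rng.normal(180, 25, (32, 32)), rng.normal(40, 15, (32, 32)))
            patches.append((np.clip(p, 0, None), p > 100))
        clf = ft.train_pixel_classifier(patches, scales=[0.0], seed=0)
        agree = [(clf.score(p) > 0.5) == lab for p, lab in patches]
        assert np.mean([a.mean() for a in agree]) >= 0.99

    def test_single_class_labels_rejected(self):
        patch = np.random.default_rng(1).uniform(0, 10, (8, 8))
        with pytest.raises(ValueError, match="single class"):
            ft.train_pixel_classifier([(patch, np.ones((8, 8), dtype=bool))])

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(2)
        patch = rng.uniform(0, 255, (16, 16))
        patches = [(patch, patch > 90)]
        w1 = ft.train_pixel_classifier(patches, seed=5).weights
        w2 = ft.train_pixel_classifier(patches, seed=5).weights
        np.testing.assert_array_equal(w1, w2)


class TestMakeMask:
    def test_fixed_threshold_zero_equals_region(self):
        channel = np.full((12, 12), 5.0)
        region = BinaryMask(np.random.default_rng(0).random((12, 12)) > 0.4)
        mask = ft.make_mask(channel, ThresholdPolicy("fixed", fixed_value=0.0), region)
        np.testing.assert_array_equal(mask.values, region.values)

    def test_threshold_above_max_gives_empty_mask(self):
        channel = np.random.default_rng(1).uniform(0, 10, (12, 12))
        mask = ft.make_mask(channel, ThresholdPolicy("fixed", fixed_value=99.0),
                            full_region((12, 12)))
        assert mask.positive_count == 0

    def test_otsu_mask_counts_bright_class(self):
        img = np.full((10, 10), 10.0)
        img[:, 5:] = 200.0
        mask = ft.make_mask(img, ThresholdPolicy("otsu"), full_region((10, 10)))
        assert mask.positive_count == int(np.sum(img == 200.0))


class TestRatios:
    def test_identity_is_100_percent(self):
        m = BinaryMask(np.pad(np.ones((10, 10), dtype=bool), 3))
        assert ft.pixel_ratio(m, m) == pytest.approx(100.0)

    def test_quarter_overlap(self):
        den = np.zeros((20, 20), dtype=bool)
        den[:10, :10] = True  # 100 px
        num = np.zeros((20, 20), dtype=bool)
        num[:5, :5] = True  # 25 px inside
        assert ft.pixel_ratio(BinaryMask(num), BinaryMask(den)) == pytest.approx(25.0)

    def test_empty_denominator_raises(self):
        with pytest.raises(ValueError, match="reference-positive"):
            ft.pixel_ratio(BinaryMask(np.ones((4, 4), dtype=bool)),
                           BinaryMask(np.zeros((4, 4), dtype=bool)))

    def test_random_masks_match_counting_oracle(self):
        rng = np.random.default_rng(4)
        a = BinaryMask(rng.random((64, 64)) > 0.5)
        b = BinaryMask(rng.random((64, 64)) > 0.3)
        expect = 100.0 * sum(1 for x, y in zip(a.values.ravel(), b.values.ravel())
                             if x and y) / b.positive_count
        assert ft.pixel_ratio(a, b) == pytest.approx(expect)

    def test_density_bounds_and_oracle(self):
        rng = np.random.default_rng(5)
        region = BinaryMask(np.tri(32, dtype=bool))  # triangular region
        mask = BinaryMask((rng.random((32, 32)) > 0.6) & region.values)
        expect = 100.0 * mask.positive_count / region.positive_count
        assert ft.pixel_density(mask, region) == pytest.approx(expect)
        assert ft.pixel_density(region, region) == pytest.approx(100.0)
        assert ft.pixel_density(BinaryMask(np.zeros((32, 32), bool)), region) == 0.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ratio_monotone_in_numerator_growth(self, seed):
        rng = np.random.default_rng(seed)
        den = BinaryMask(rng.random((16, 16)) > 0.4)
        if den.positive_count == 0:
            return
        small = rng.random((16, 16)) > 0.7
        grown = small | (rng.random((16, 16)) > 0.7)
        r1 = ft.pixel_ratio(BinaryMask(small), den)
        r2 = ft.pixel_ratio(BinaryMask(grown), den)
        assert 0.0 <= r1 <= r2 <= 100.0


class TestRatiometricMap:
    def test_equal_channels_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        ch = np.where(rng.random((32, 32)) > 0.5, 200.0, 5.0)
        rmap = ft.ratiometric_map(ch, ch, full_region(ch.shape))
        defined = np.isfinite(rmap.values)
        assert defined.any()
        assert np.allclose(rmap.values[defined], 1.0)

    def test_doubled_channel_gives_ratio_two(self):
        rng = np.random.default_rng(1)
        den = np.where(rng.random((32, 32)) > 0.5, 120.0, 4.0)
        rmap = ft.ratiometric_map(2.0 * den, den, full_region(den.shape))
        assert np.allclose(rmap.values[np.isfinite(rmap.values)], 2.0)

    def test_undefined_outside_joint_mask(self):
        rng = np.random.default_rng(2)
        a = np.where(rng.random((32, 32)) > 0.5, 150.0, 2.0)
        b = np.where(rng.random((32, 32)) > 0.5, 150.0, 2.0)
        rmap = ft.ratiometric_map(a, b, full_region((32, 32)))
        np.testing.assert_array_equal(np.isfinite(rmap.values), rmap.mask.values)

    def test_common_scale_invariance(self):
        rng = np.random.default_rng(3)
        a = np.where(rng.random((24, 24)) > 0.5, 150.0, 2.0) * rng.uniform(0.5, 1.5, (24, 24))
        b = np.where(rng.random((24, 24)) > 0.5, 150.0, 2.0) * rng.uniform(0.5, 1.5, (24, 24))
        r1 = ft.ratiometric_map(a, b, full_region((24, 24)))
        r2 = ft.ratiometric_map(5.0 * a, 5.0 * b, full_region((24, 24)))
        np.testing.assert_allclose(r1.values, r2.values, equal_nan=True)

    def test_mean_matches_per_pixel_oracle(self, invasive_sample, config):
        img = invasive_sample.image
        region = full_region(img.shape)
        rmap = ft.ratiometric_map(img["FnBPA5"], img["FN"], region)
        sel = rmap.mask.values
        oracle = np.mean([img["FnBPA5"][r, c] / img["FN"][r, c]
                          for r, c in zip(*np.nonzero(sel[:128, :128]))])
        sub_mean = np.nanmean(rmap.values[:128, :128])
        assert sub_mean == pytest.approx(oracle)
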