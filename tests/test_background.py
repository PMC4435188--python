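import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frame
from oracles import oracle_histograms, oracle_rgb_to_hsi_pixel, shoelace_area

from nestsentry.background import (AppearanceHistogram, BackgroundConfig,
                                   BackgroundModel, BackgroundThresholds,
                                   EmptyRegionError, UpdateParams,
                                   classify_foreground, compute_histograms,
                                   hsi_to_rgb, initial_reference_region,
                                   rgb_to_hsi, saliency_gated_mask,
                                   update_model)
from nestsentry.saliency import SaliencyMap


class TestHSIConversion:
    def test_gray_pixel_has_zero_saturation_and_undefined_hue(self):
        hsi = rgb_to_hsi(make_frame(np.full((2, 2, 3), 0.5)))
        assert np.allclose(hsi.intensity, 0.5)
        assert np.allclose(hsi.saturation, 0.0)
        assert not hsi.hue_defined.any()

    def test_pure_red_conversion_identity(self):
        px = np.zeros((1, 1, 3))
        px[0, 0] = (1.0, 0.0, 0.0)
        hsi = rgb_to_hsi(px)
        assert hsi.hue[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert hsi.saturation[0, 0] == pytest.approx(1.0)
        assert hsi.intensity[0, 0] == pytest.approx(1.0 / 3.0)

    def test_matches_scalar_arccos_oracle(self, rng):
        px = rng.random((8, 8, 3))
        px[0, 0] = (0.2, 0.6, 0.4)  # worked example from the formula
        hsi = rgb_to_hsi(px)
        for i in range(8):
            for j in range(8):
                hue, sat, inten = oracle_rgb_to_hsi_pixel(*px[i, j])
                assert hsi.intensity[i, j] == pytest.approx(inten, abs=1e-6)
                assert hsi.saturation[i, j] == pytest.approx(sat, abs=1e-6)
                if hue is None:
                    assert not hsi.hue_defined[i, j]
                else:
                    assert hsi.hue_defined[i, j]
                    assert hsi.hue[i, j] == pytest.approx(hue, abs=1e-6)

    def test_round_trips_through_inverse_conversion(self, rng):
        # in-gamut combinations only: the leading channel i*(1+2s) must
        # stay below 1 or the inverse clips
        hue = rng.random((16, 16))
        sat = rng.uniform(0.2, 0.5, (16, 16))
        inten = rng.uniform(0.1, 0.45, (16, 16))
        back = rgb_to_hsi(hsi_to_rgb(hue, sat, inten))
        assert np.allclose(back.intensity, inten, atol=1e-6)
        assert np.allclose(back.saturation, sat, atol=1e-6)
        dh = np.abs(back.hue - hue)
        assert np.allclose(np.minimum(dh, 1 - dh), 0.0, atol=1e-6)


class TestReferenceRegion:
    def test_default_trapezoid_area_matches_shoelace_formula(self):
        region = initial_reference_region(640, 480)
        analytic = shoelace_area(region.polygon)
        assert abs(region.mask.sum() - analytic) <= 640  # one raster row

    def test_full_frame_config_covers_every_pixel(self):
        cfg = BackgroundConfig(trapezoid_bottom_frac=1.0, trapezoid_top_frac=1.0,
                               trapezoid_height_frac=1.0)
        region = initial_reference_region(64, 48, cfg)
        assert region.mask.all()

    def test_degenerate_trapezoid_rejected(self):
        cfg = BackgroundConfig(trapezoid_bottom_frac=0.0, trapezoid_top_frac=0.0)
        with pytest.raises(ValueError):
            initial_reference_region(640, 480, cfg)


class TestHistograms:
    def test_uniform_region_concentrates_in_single_bins(self):
        px = np.full((8, 8, 3), (0.6, 0.3, 0.2))
        hist = compute_histograms(rgb_to_hsi(px), np.ones((8, 8), bool), 64)
        assert np.isclose(hist.hue_bins.max(), 1.0)
        assert np.isclose(hist.intensity_bins.max(), 1.0)

    def test_two_equal_colors_split_mass_evenly(self):
        px = np.zeros((2, 8, 3))
        px[0] = (0.8, 0.2, 0.2)
        px[1] = (0.2, 0.2, 0.8)
        hist = compute_histograms(rgb_to_hsi(px), np.ones((2, 8), bool), 64)
        assert sorted(hist.hue_bins[hist.hue_bins > 0]) == [0.5, 0.5]

    def test_matches_per_pixel_counting_oracle(self, rng):
        px = rng.random((16, 16, 3))
        mask = rng.random((16, 16)) > 0.3
        hsi = rgb_to_hsi(px)
        hist = compute_histograms(hsi, mask, 32)
        hue_o, int_o = oracle_histograms(hsi.hue, hsi.hue_defined,
                                         hsi.intensity, mask, 32)
        assert np.max(np.abs(hist.hue_bins - hue_o)) < 1e-6
        assert np.max(np.abs(hist.intensity_bins - int_o)) < 1e-6

    def test_empty_mask_raises_empty_region(self):
        hsi = rgb_to_hsi(np.full((4, 4, 3), 0.5))
        with pytest.raises(EmptyRegionError):
            compute_histograms(hsi, np.zeros((4, 4), bool), 64)


class TestSaliencyGate:
    def test_zero_saliency_gates_nothing(self):
        mask = saliency_gated_mask(SaliencyMap(np.zeros((10, 10))))
        assert mask.all()

    def test_gate_excludes_exactly_suprathreshold_pixels(self):
        v = np.zeros((10, 10))
        v[2:5, 2:5] = 1.0
        v[7, 7] = 0.6
        mask = saliency_gated_mask(SaliencyMap(v), gate_fraction=0.5)
        assert not mask[3, 3] and not mask[7, 7]
        assert mask[0, 0]
        assert (~mask).sum() == 10

    def test_gating_never_adds_mass_from_excluded_pixels(self):
        """Hue bins present only inside the excluded region stay empty."""
        px = np.full((16, 16, 3), (0.2, 0.7, 0.3))
        px[4:8, 4:8] = (0.8, 0.2, 0.2)  # 'obstacle' hue, to be gated out
        hsi = rgb_to_hsi(px)
        sal = np.zeros((16, 16))
        sal[4:8, 4:8] = 1.0
        gate = saliency_gated_mask(SaliencyMap(sal), 0.5)
        hist = compute_histograms(hsi, gate, 64)
        obstacle_bin = int(np.floor(hsi.hue[5, 5] * 64)) % 64
        assert hist.hue_bins[obstacle_bin] == 0.0


class TestIncrementalUpdate:
    def test_alpha_one_replaces_the_model(self):
        prev = AppearanceHistogram([1.0, 0.0], [0.0, 1.0], 2)
        cur = AppearanceHistogram([0.0, 1.0], [1.0, 0.0], 2)
        out = update_model(prev, cur, UpdateParams(alpha=1.0))
        assert np.allclose(out.hue_bins, [0.0, 1.0])
        assert np.allclose(out.intensity_bins, [1.0, 0.0])

    def test_half_weight_blend(self):
        prev = AppearanceHistogram([1.0, 0.0], [1.0, 0.0], 2)
        cur = AppearanceHistogram([0.0, 1.0], [0.0, 1.0], 2)
        out = update_model(prev, cur, UpdateParams(alpha=0.5))
        assert np.allclose(out.hue_bins, [0.5, 0.5])

    def test_bin_count_mismatch_rejected(self):
        a = AppearanceHistogram(np.full(4, 0.25), np.full(4, 0.25), 4)
        b = AppearanceHistogram(np.full(8, 0.125), np.full(8, 0.125), 8)
        with pytest.raises(ValueError):
            update_model(a, b, UpdateParams())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.05, 0.95))
    def test_repeated_updates_contract_geometrically(self, seed, alpha):
        """|uHist_t - current|_1 <= beta^t |uHist_0 - current|_1, exactly the
        closed form of the linear recursion, and every iterate stays
        normalized."""
        r = np.random.default_rng(seed)
        def rand_hist():
            h = r.random(16) + 1e-3
            i = r.random(16) + 1e-3
            return AppearanceHistogram(h / h.sum(), i / i.sum(), 16)
        model, target = rand_hist(), rand_hist()
        params = UpdateParams(alpha=alpha)
        d0 = np.abs(model.hue_bins - target.hue_bins).sum()
        for t in range(1, 8):
            model = update_model(model, target, params)
            assert model.hue_bins.sum() == pytest.approx(1.0, abs=1e-9)
            assert model.intensity_bins.sum() == pytest.approx(1.0, abs=1e-9)
            dt = np.abs(model.hue_bins - target.hue_bins).sum()
            assert dt <= params.beta ** t * d0 + 1e-9


class TestForegroundClassification:
    def test_frame_matching_the_model_has_empty_foreground(self):
        px = np.full((32, 32, 3), (0.25, 0.55, 0.35))
        hsi = rgb_to_hsi(px)
        model = compute_histograms(hsi, np.ones((32, 32), bool), 64)
        fg = classify_foreground(hsi, model)
        assert not fg.any()

    def test_novel_hue_patch_is_flagged(self):
        px = np.full((32, 32, 3), (0.25, 0.55, 0.35))
        hsi = rgb_to_hsi(px)
        model = compute_histograms(hsi, np.ones((32, 32), bool), 64)
        px[10:14, 10:14] = (0.7, 0.3, 0.2)  # same intensity, different hue
        fg = classify_foreground(rgb_to_hsi(px), model)
        assert fg[10:14, 10:14].all()
        assert fg.sum() == 16

    def test_unnormalized_model_rejected(self):
        bad = AppearanceHistogram(np.ones(4), np.ones(4), 4, normalized=False)
        hsi = rgb_to_hsi(np.full((2, 2, 3), 0.5))
        with pytest.raises(ValueError):
            classify_foreground(hsi, bad)

    def test_foreground_recovers_after_global_intensity_ramp(self):
        """Scaling the whole scene darker and back, with the model updated
        each frame, leaves only a transient foreground response."""
        rng = np.random.default_rng(7)
        base = np.clip(0.5 + 0.05 * rng.standard_normal((48, 64)), 0, 1)
        hue = np.full((48, 64), 0.33)
        sat = np.full((48, 64), 0.45)
        model = BackgroundModel(BackgroundConfig(update_region="full"))
        zero_sal = SaliencyMap(np.zeros((48, 64)))
        factors = [1.0] * 5 + list(1 - 0.4 * (1 - np.abs(np.linspace(-1, 1, 21)))) \
            + [1.0] * 10
        fracs = []
        for f in factors:
            hsi = rgb_to_hsi(hsi_to_rgb(hue, sat, base * f))
            if model.histogram is None:
                model.initialize(hsi)
            else:
                model.update(hsi, zero_sal)
            fracs.append(classify_foreground(hsi, model.histogram,
                                             model.thresholds).mean())
        assert max(fracs[-5:]) < 0.01  # recovered after the ramp


class TestBackgroundThresholds:
    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_threshold_bounds(self, bad):
        with pytest.raises(ValueError):
            BackgroundThresholds(hue_threshold=bad)
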