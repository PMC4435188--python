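import numpy as np
import pytest

from conftest import make_frame
from oracles import (oracle_center_surround, oracle_gabor_response,
                     oracle_pyramid)

from nestsentry.saliency import (SaliencyConfig, build_pyramid,
                                 center_surround, compute_feature_maps,
                                 compute_saliency, itti_normalize)

NEAREST = SaliencyConfig(upsample_order=0)


class TestPyramid:
    def test_constant_input_stays_constant_at_every_level(self):
        pyr = build_pyramid(np.full((64, 64), 0.5))
        assert pyr.depth == 9
        for level in pyr.levels:
            assert np.allclose(level, 0.5)

    def test_dyadic_level_sizes(self):
        pyr = build_pyramid(np.zeros((512, 512)))
        for s, level in enumerate(pyr.levels):
            assert level.shape == (512 // 2 ** s, 512 // 2 ** s)

    def test_odd_sizes_round_up(self):
        pyr = build_pyramid(np.zeros((45, 33)))
        assert pyr[1].shape == (23, 17)
        assert pyr[2].shape == (12, 9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_pyramid(np.zeros((0, 4)))

    def test_levels_match_direct_convolution_oracle(self, rng):
        """Separable smoothing + decimation equals brute-force 2-D windows."""
        img = rng.random((32, 32))
        img[10, 20] = 5.0  # bright impulse exercises the border rule too
        expected = oracle_pyramid(img)
        pyr = build_pyramid(img)
        for lv, (a, b) in enumerate(zip(pyr.levels, expected)):
            assert np.max(np.abs(a - b)) < 1e-6, f"level {lv}"


class TestCenterSurround:
    def test_constant_pyramid_gives_zero_feature_map(self):
        pyr = build_pyramid(np.full((64, 64), 0.3))
        fm = center_surround(pyr, 2, 5)
        assert np.allclose(fm.values, 0.0, atol=1e-9)

    def test_surround_must_be_coarser_than_center(self):
        pyr = build_pyramid(np.zeros((64, 64)))
        with pytest.raises(ValueError):
            center_surround(pyr, 3, 3)
        with pytest.raises(ValueError):
            center_surround(pyr, 4, 2)

    def test_bright_square_peak_inside_square_footprint(self):
        img = np.zeros((32, 32))
        img[12:16, 12:16] = 1.0
        fm = center_surround(build_pyramid(img), 2, 5, cfg=NEAREST)
        r, c = np.unravel_index(np.argmax(fm.values), fm.values.shape)
        # footprint of rows/cols 12..15 at scale 2 is 3..3
        assert 2 <= r <= 4 and 2 <= c <= 4
        oracle = oracle_center_surround(img, 2, 5)
        assert np.max(np.abs(fm.values - oracle)) < 1e-6

    def test_matches_oracle_on_random_input(self, rng):
        img = rng.random((64, 64))
        for c, s in [(2, 5), (3, 6), (4, 8)]:
            fm = center_surround(build_pyramid(img), c, s, cfg=NEAREST)
            oracle = oracle_center_surround(img, c, s)
            assert np.max(np.abs(fm.values - oracle)) < 1e-6, (c, s)

    def test_interpolation_choice_shifts_values_below_ten_percent(self):
        """Nearest vs bilinear surround upsampling is a bounded perturbation."""
        img = np.zeros((32, 32))
        img[12:16, 12:16] = 1.0
        pyr = build_pyramid(img)
        near = center_surround(pyr, 2, 5, cfg=NEAREST).values
        bilin = center_surround(pyr, 2, 5, cfg=SaliencyConfig(upsample_order=1)).values
        assert np.max(np.abs(near - bilin)) < 0.10 * near.max()


class TestFeatureMaps:
    def test_gray_frame_has_zero_color_opponency(self, gray_frame):
        for fm in compute_feature_maps(gray_frame):
            if fm.channel in ("red-green", "blue-yellow"):
                assert np.allclose(fm.values, 0.0, atol=1e-9)

    def test_uniform_frame_has_all_zero_features(self, uniform_frame):
        for fm in compute_feature_maps(uniform_frame):
            assert np.allclose(fm.values, 0.0, atol=1e-9)

    def test_horizontal_bar_wins_zero_degree_orientation(self):
        """A horizontal bar drives the 0-degree channel hardest, matching a
        direct single-scale Gabor oracle."""
        img = np.zeros((128, 128))
        img[60:66, 10:118] = 1.0
        frame = make_frame(np.stack([img] * 3, axis=-1))
        maxima = {}
        for fm in compute_feature_maps(frame):
            if fm.channel.startswith("orientation") and \
                    (fm.center_scale, fm.surround_scale) == (2, 5):
                maxima[fm.channel] = fm.values.max()
        assert max(maxima, key=maxima.get) == "orientation-0"
        oracle = {t: oracle_gabor_response(img, t).max() for t in (0, 45, 90, 135)}
        assert max(oracle, key=oracle.get) == 0


class TestSaliencyMap:
    def test_uniform_frame_yields_all_zero_map(self, uniform_frame):
        sal = compute_saliency(uniform_frame)
        assert np.allclose(sal.values, 0.0)

    def test_map_bounded_and_registered_to_frame(self, rng):
        frame = make_frame(rng.random((96, 128, 3)))
        sal = compute_saliency(frame)
        assert sal.values.shape == (96, 128)
        assert sal.values.min() >= 0.0 and sal.values.max() <= 1.0

    def test_high_contrast_box_is_globally_most_salient(self):
        """A single odd object on homogeneous ground takes the maximum."""
        img = np.full((240, 320, 3), (0.3, 0.5, 0.3))
        img[100:120, 200:230] = (0.9, 0.1, 0.1)
        sal = compute_saliency(make_frame(img))
        r, c = np.unravel_index(np.argmax(sal.values), sal.values.shape)
        assert 90 <= r <= 130 and 190 <= c <= 240

    def test_blob_on_clean_half_outscores_blob_in_clutter(self):
        """The peak-promoting normalization rewards isolated blobs."""
        rng = np.random.default_rng(5)
        img = np.full((256, 256, 3), 0.5)
        for _ in range(25):
            r, c = rng.integers(10, 246), rng.integers(10, 118)
            img[r - 4:r + 4, c - 4:c + 4] = 0.9
        img[120:128, 60:68] = 0.1
        img[120:128, 188:196] = 0.1
        sal = compute_saliency(make_frame(np.clip(img, 0, 1))).values
        clutter = sal[116:132, 54:74].max()
        clean = sal[116:132, 182:202].max()
        assert clean >= clutter

    def test_translation_by_working_scale_stride_moves_argmax(self):
        """Shifting the input by one working-scale stride (16 px) moves the
        saliency peak by the same amount, within one working-scale pixel."""
        base = np.full((240, 320, 3), 0.4)
        base[96:108, 128:140] = (0.95, 0.9, 0.1)
        shifted = np.full((240, 320, 3), 0.4)
        shifted[112:124, 144:156] = (0.95, 0.9, 0.1)
        p1 = np.unravel_index(np.argmax(compute_saliency(make_frame(base)).values),
                              (240, 320))
        p2 = np.unravel_index(np.argmax(compute_saliency(make_frame(shifted)).values),
                              (240, 320))
        assert abs((p2[0] - p1[0]) - 16) <= 16
        assert abs((p2[1] - p1[1]) - 16) <= 16


class TestNormalization:
    def test_constant_map_normalizes_to_zero(self):
        assert np.allclose(itti_normalize(np.full((20, 20), 3.0)), 0.0)

    def test_single_peak_keeps_full_weight(self):
        m = np.zeros((20, 20))
        m[10, 10] = 1.0
        out = itti_normalize(m)
        assert out.max() == pytest.approx(1.0)

    def test_many_equal_peaks_are_suppressed(self):
        m = np.zeros((24, 24))
        m[4::8, 4::8] = 1.0  # grid of identical peaks
        out = itti_normalize(m)
        assert out.max() < 0.05
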