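"""Preprocessing operators: restoration quality, invariants, edge rules."""
from dataclasses import replace

import numpy as np
import pytest

from lesionforge import LabeledImage, LesionSpec, generate_lesion
from lesionforge.exceptions import ValidationError
from lesionforge.preprocess import (PreprocessConfig, convert_color_space,
                                    equalize_adaptive, filter_adaptive_local,
                                    filter_adaptive_median, remove_hairs,
                                    resize_bilinear, run_pipeline, to_rgb)


def mse(a, b):
    return float(((np.asarray(a, float) - np.asarray(b, float)) ** 2).mean())


class TestResize:
    def test_identity_resize(self, clean_image, pre_cfg):
        out = resize_bilinear(clean_image, pre_cfg)
        assert np.array_equal(out.pixels, clean_image.pixels)
        assert np.array_equal(out.mask, clean_image.mask)

    def test_constant_image_preserved(self):
        img = LabeledImage(pixels=np.full((64, 64, 3), 131, dtype=np.uint8))
        out = resize_bilinear(img, PreprocessConfig(target_height=32, target_width=32))
        assert out.pixels.shape == (32, 32, 3)
        assert np.all(out.pixels == 131)

    def test_mask_fraction_roughly_preserved(self, clean_image):
        out = resize_bilinear(clean_image, PreprocessConfig(target_height=32,
                                                            target_width=32))
        assert out.mask.shape == (32, 32)
        assert set(np.unique(out.mask)) <= {0, 1}
        assert abs(out.foreground_fraction() - clean_image.foreground_fraction()) <= 0.05

    def test_nonpositive_target_rejected(self, clean_image):
        with pytest.raises(ValidationError):
            resize_bilinear(clean_image, PreprocessConfig(target_height=0,
                                                          target_width=32))


class TestColorSpaces:
    def test_pure_red_hsv(self):
        img = LabeledImage(pixels=np.full((16, 16, 3), (255, 0, 0), dtype=np.uint8))
        hsv = convert_color_space(img, "HSV")
        assert hsv.pixels[0, 0, 0] == pytest.approx(0.0)
        assert hsv.pixels[0, 0, 1] == pytest.approx(1.0)

    def test_gray_pixel_has_zero_saturation(self):
        img = LabeledImage(pixels=np.full((8, 8, 3), 93, dtype=np.uint8))
        assert convert_color_space(img, "HSV").pixels[..., 1].max() == 0.0

    def test_hsv_round_trip_within_one_level(self, clean_image):
        back = to_rgb(convert_color_space(clean_image, "HSV"))
        assert np.abs(back.pixels.astype(int) - clean_image.pixels.astype(int)).max() <= 1

    def test_lab_round_trip_within_two_levels(self, clean_image):
        back = to_rgb(convert_color_space(clean_image, "LAB"))
        assert np.abs(back.pixels.astype(int) - clean_image.pixels.astype(int)).max() <= 2

    def test_unknown_space_lists_supported(self, clean_image):
        with pytest.raises(ValidationError, match="RGB"):
            convert_color_space(clean_image, "XYZ")


class TestEqualize:
    def test_constant_image_untouched(self, pre_cfg):
        img = LabeledImage(pixels=np.full((32, 32, 3), 77, dtype=np.uint8))
        out = equalize_adaptive(img, pre_cfg)
        assert np.array_equal(out.pixels, img.pixels)

    def test_contrast_increases_on_low_contrast_lesion(self, pre_cfg):
        img = generate_lesion(LesionSpec(seed=2))
        # squash contrast toward the middle of the range
        squashed = img.with_pixels((img.pixels * 0.3 + 100).astype(np.uint8))
        out = equalize_adaptive(squashed, pre_cfg)
        assert out.pixels.std() >= squashed.pixels.std()

    def test_mask_unchanged(self, clean_image, pre_cfg):
        out = equalize_adaptive(clean_image, pre_cfg)
        assert np.array_equal(out.mask, clean_image.mask)


class TestAdaptiveMedian:
    def test_identity_on_impulse_free_image(self, clean_image, pre_cfg):
        out = filter_adaptive_median(clean_image, pre_cfg)
        assert np.array_equal(out.pixels, clean_image.pixels)

    @pytest.mark.parametrize("seed", [0, 3, 5])
    def test_restores_90pct_of_5pct_impulse_noise(self, seed, pre_cfg):
        clean = generate_lesion(LesionSpec(seed=seed))
        noisy = generate_lesion(LesionSpec(seed=seed, impulse_noise_prob=0.05))
        corrupted = np.any(noisy.pixels != clean.pixels, axis=2)
        restored = filter_adaptive_median(noisy, pre_cfg)
        err = np.abs(restored.pixels.astype(int) - clean.pixels.astype(int)).max(axis=2)
        assert (err[corrupted] <= 10).mean() >= 0.90

    def test_single_impulse_in_flat_field(self, pre_cfg):
        px = np.full((32, 32), 100, dtype=np.uint8)
        px[16, 16] = 255
        out = filter_adaptive_median(LabeledImage(pixels=px), pre_cfg)
        assert out.pixels[16, 16] == 100
        untouched = np.ones((32, 32), bool)
        untouched[16, 16] = False
        assert np.all(out.pixels[untouched] == 100)

    def test_even_window_rejected(self, clean_image):
        with pytest.raises(ValidationError, match="odd"):
            filter_adaptive_median(clean_image, PreprocessConfig(median_max_window=6))


class TestAdaptiveLocal:
    def test_zero_noise_variance_is_identity(self, clean_image):
        cfg = PreprocessConfig(local_noise_variance=0.0)
        out = filter_adaptive_local(clean_image, cfg)
        assert np.array_equal(out.pixels, clean_image.pixels)

    def test_ratio_one_returns_local_mean(self):
        # iid noise around a constant: local variance ~= noise variance, so the
        # filter should behave like the local mean almost everywhere
        rng = np.random.default_rng(0)
        px = (100 + rng.normal(0, 10, (64, 64))).astype(np.float64)
        img = LabeledImage(pixels=px)
        out = filter_adaptive_local(img, PreprocessConfig(local_noise_variance=1e6))
        from scipy.ndimage import uniform_filter
        assert np.allclose(out.pixels, uniform_filter(px, 7, mode="reflect"), atol=1e-6)

    @pytest.mark.parametrize("seed", [1, 4])
    def test_mse_strictly_decreases_on_speckle(self, seed, pre_cfg):
        clean = generate_lesion(LesionSpec(seed=seed))
        speck = generate_lesion(LesionSpec(seed=seed, speckle_variance=0.01))
        out = filter_adaptive_local(speck, pre_cfg)
        assert mse(out.pixels, clean.pixels) < mse(speck.pixels, clean.pixels)


class TestHairRemoval:
    @pytest.mark.parametrize("seed", [0, 2, 5])
    def test_hair_free_image_nearly_untouched(self, seed, pre_cfg):
        clean = generate_lesion(LesionSpec(seed=seed))
        out = remove_hairs(clean, pre_cfg)
        assert (out.pixels != clean.pixels).mean() < 0.01

    @pytest.mark.parametrize("seed", [0, 2, 5])
    def test_mse_to_hair_free_twin_strictly_reduced(self, seed, pre_cfg):
        clean = generate_lesion(LesionSpec(seed=seed))
        hairy = generate_lesion(LesionSpec(seed=seed, hair_count=5))
        out = remove_hairs(hairy, pre_cfg)
        assert mse(out.pixels, clean.pixels) < mse(hairy.pixels, clean.pixels)

    def test_mask_identical(self, pre_cfg):
        hairy = generate_lesion(LesionSpec(seed=1, hair_count=5))
        out = remove_hairs(hairy, pre_cfg)
        assert np.array_equal(out.mask, hairy.mask)


class TestPipeline:
    def test_operations_preserve_range_and_shape(self, clean_image, pre_cfg):
        for op in (filter_adaptive_median, filter_adaptive_local,
                   equalize_adaptive, remove_hairs):
            out = op(clean_image, pre_cfg)
            assert out.pixels.shape == clean_image.pixels.shape
            assert out.pixels.min() >= 0 and out.pixels.max() <= 255
            assert np.array_equal(out.mask, clean_image.mask)

    def test_pipeline_without_equalize_is_idempotent_within_3_levels(
            self, clean_image, pre_cfg):
        # adaptive equalisation re-stretches tile histograms on every pass and
        # is inherently non-idempotent; the restoration stages are
        order = ("resize", "color", "hairs", "median", "local")
        p1 = run_pipeline(clean_image, pre_cfg, order)
        p2 = run_pipeline(p1, pre_cfg, order)
        assert np.abs(p2.pixels.astype(int) - p1.pixels.astype(int)).max() <= 3

    def test_default_pipeline_runs_and_keeps_mask(self, clean_image, pre_cfg):
        out = run_pipeline(clean_image, pre_cfg)
        assert out.pixels.shape == clean_image.pixels.shape
        assert np.array_equal(out.mask, clean_image.mask)

    def test_unknown_stage_rejected(self, clean_image, pre_cfg):
        with pytest.raises(ValidationError, match="stage"):
            run_pipeline(clean_image, pre_cfg, ("resize", "sharpen"))
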