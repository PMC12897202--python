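"""Pre-processing chain: saturation rescale, CLAHE, adaptive Wiener,
Gaussian smoothing, ROI extraction."""

import numpy as np
import pytest

from mitotexture.image import Image2D, read_image, write_image
from mitotexture.preprocess import (PreprocessConfig, clahe, extract_rois,
                                    gaussian_smooth, preprocess_image,
                                    saturate_rescale, wiener_adaptive)
from oracles import o_tile_equalize, o_wiener


class TestImageIO:
    def test_roundtrip_preserves_pixels(self, tmp_path, rng):
        for depth, dtype in ((8, np.uint8), (16, np.uint16)):
            arr = rng.integers(0, 2**depth, size=(69, 69)).astype(dtype)
            path = tmp_path / f"img{depth}.tiff"
            write_image(Image2D(arr, bit_depth=depth), path)
            back = read_image(path)
            assert back.bit_depth == depth
            np.testing.assert_array_equal(back.pixels, arr)

    def test_zero_image_reads_as_zero(self, tmp_path):
        write_image(Image2D(np.zeros((69, 69), dtype=np.uint8)), tmp_path / "z.tiff")
        img = read_image(tmp_path / "z.tiff")
        assert img.bit_depth == 8 and not img.pixels.any()

    def test_rgb_without_channel_is_rejected(self, tmp_path):
        import tifffile
        tifffile.imwrite(tmp_path / "rgb.tiff",
                         np.zeros((16, 16, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="channel"):
            read_image(tmp_path / "rgb.tiff")
        img = read_image(tmp_path / "rgb.tiff", channel=0)
        assert img.shape == (16, 16)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_image(tmp_path / "nope.tiff")


class TestSaturateRescale:
    def test_constant_image_unchanged(self):
        img = Image2D(np.full((10, 10), 40, dtype=np.uint8))
        out = saturate_rescale(img, 0.01, 0.01)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_ramp_with_one_percent_saturation(self):
        # 100 px ramp 0..99: linear quantiles give q_low=0.99, q_high=98.01,
        # so 1 -> ~0.026 (rounds to 0) and 98 -> ~254.97 (rounds to 255)
        ramp = np.arange(100, dtype=np.uint8).reshape(10, 10)
        out = saturate_rescale(Image2D(ramp), 0.01, 0.01)
        rounded = np.rint(out.pixels)
        assert rounded.flat[1] == 0
        assert rounded.flat[98] == 255
        # interior linearity
        interior = out.pixels.ravel()[2:98]
        diffs = np.diff(interior)
        np.testing.assert_allclose(diffs, diffs[0], rtol=1e-9)

    def test_output_spans_full_range(self, rng):
        arr = rng.integers(20, 200, size=(32, 32)).astype(np.uint8)
        out = saturate_rescale(Image2D(arr), 0.01, 0.01)
        assert out.pixels.min() == 0.0
        assert out.pixels.max() == 255.0


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = Image2D(np.full((32, 32), 77, dtype=np.uint8))
        out = clahe(img, tiles=(4, 4), clip=0.01)
        assert np.unique(out.pixels).size == 1

    def test_two_tone_single_tile_preserves_level_count(self, rng):
        arr = np.where(rng.random((32, 32)) < 0.25, 60, 180).astype(np.uint8)
        out = clahe(Image2D(arr), tiles=(1, 1), clip=0.01)
        assert np.unique(out.pixels).size == 2

    def test_unclipped_single_tile_equals_global_equalization(self, rng):
        arr = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        out = clahe(Image2D(arr), tiles=(1, 1), clip=1.0, nbins=256)
        luts = o_tile_equalize(arr.astype(float), (1, 1), 256, 255.0)
        expected = luts[0, 0][np.clip((arr / 255.0 * 256).astype(int), 0, 255)]
        np.testing.assert_allclose(out.pixels, expected, rtol=1e-12)

    def test_unclipped_tile_centers_match_per_tile_equalizer(self, rng):
        # 66x66 with 2x2 tiles -> 33 px tiles with integer centers (16, 49);
        # at a tile center the bilinear blend reduces to that tile's own map
        arr = rng.integers(0, 256, size=(66, 66)).astype(np.uint8)
        out = clahe(Image2D(arr), tiles=(2, 2), clip=1.0, nbins=256)
        luts = o_tile_equalize(arr.astype(float), (2, 2), 256, 255.0)
        for tr, r in enumerate((16, 49)):
            for tc, c in enumerate((16, 49)):
                b = min(int(arr[r, c] / 255.0 * 256), 255)
                assert out.pixels[r, c] == pytest.approx(luts[tr, tc, b], rel=1e-12)

    def test_oversized_tiling_falls_back_to_single_tile(self):
        img = Image2D(np.arange(64, dtype=np.uint8).reshape(8, 8))
        with pytest.warns(UserWarning, match="single tile"):
            out = clahe(img, tiles=(16, 16))
        assert out.shape == (8, 8)


class TestWiener:
    def test_constant_image_unchanged(self):
        img = Image2D(np.full((12, 12), 99, dtype=np.uint8))
        out = wiener_adaptive(img, 3)
        np.testing.assert_allclose(out.pixels, 99.0)

    def test_impulse_is_attenuated(self):
        arr = np.zeros((15, 15), dtype=np.uint8)
        arr[7, 7] = 200
        out = wiener_adaptive(Image2D(arr), 3)
        assert out.pixels[7, 7] < 200

    @pytest.mark.parametrize("window", [3, 5])
    def test_matches_bruteforce_formula(self, rng, window):
        arr = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        out = wiener_adaptive(Image2D(arr), window)
        ref = o_wiener(arr.astype(float), window)
        np.testing.assert_allclose(out.pixels, ref, rtol=1e-9, atol=1e-9)

    def test_never_amplifies_pure_noise_variance(self):
        for seed in range(5):
            r = np.random.default_rng(seed)
            arr = r.integers(80, 176, size=(32, 32)).astype(np.uint8)
            out = wiener_adaptive(Image2D(arr), 3)
            assert out.pixels.var() <= arr.astype(float).var()


class TestGaussian:
    def test_constant_unchanged(self):
        img = Image2D(np.full((10, 10), 42, dtype=np.uint8))
        np.testing.assert_allclose(gaussian_smooth(img, 0.5).pixels, 42.0)

    def test_mean_conservation(self, rng):
        arr = rng.integers(0, 256, size=(33, 33)).astype(np.uint8)
        out = gaussian_smooth(Image2D(arr), 0.5)
        assert out.pixels.mean() == pytest.approx(arr.mean(), rel=1e-9)

    def test_ramp_preserved_in_interior(self):
        ramp = np.tile(np.arange(40, dtype=np.uint8), (40, 1))
        out = gaussian_smooth(Image2D(ramp), 0.5)
        np.testing.assert_allclose(out.pixels[10:-10, 10:-10],
                                   ramp[10:-10, 10:-10].astype(float), atol=1e-6)


class TestExtractRois:
    def test_center_crop_of_exact_size_image(self):
        arr = np.arange(69 * 69, dtype=np.uint16).reshape(69, 69)
        img = Image2D(arr, bit_depth=16)
        (roi,) = extract_rois(img, [(34, 34)], size=69)
        np.testing.assert_array_equal(roi.pixels, arr)

    def test_grid_crops_match_manual_slicing(self, rng):
        arr = rng.integers(0, 256, size=(200, 200)).astype(np.uint8)
        img = Image2D(arr)
        rois = extract_rois(img, "grid", size=69)
        assert len(rois) == 4
        for k, (r, c) in enumerate([(0, 0), (0, 69), (69, 0), (69, 69)]):
            np.testing.assert_array_equal(rois[k].pixels, arr[r:r + 69, c:c + 69])

    def test_out_of_bounds_center_is_reported(self):
        img = Image2D(np.zeros((100, 100), dtype=np.uint8))
        with pytest.raises(ValueError, match=r"\(10, 50\)"):
            extract_rois(img, [(10, 50)], size=69)


class TestFullChain:
    def test_constant_in_constant_out(self):
        img = Image2D(np.full((69, 69), 120, dtype=np.uint8))
        out = preprocess_image(img)
        assert np.unique(out.pixels).size == 1

    def test_shape_and_dtype_family_preserved(self, rng):
        arr = rng.integers(0, 2**16, size=(69, 69)).astype(np.uint16)
        out = preprocess_image(Image2D(arr, bit_depth=16))
        assert out.shape == (69, 69)
        assert out.pixels.dtype == np.uint16
        assert out.bit_depth == 16

    def test_chain_is_deterministic(self, rng):
        arr = rng.integers(0, 256, size=(69, 69)).astype(np.uint8)
        cfg = PreprocessConfig()
        a = preprocess_image(Image2D(arr), cfg)
        b = preprocess_image(Image2D(arr.copy()), cfg)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(sat_low_frac=0.6)
        with pytest.raises(ValueError):
            PreprocessConfig(wiener_window=4)
        with pytest.raises(ValueError):
            PreprocessConfig(gauss_sigma=0.0)
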