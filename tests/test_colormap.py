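"""Colormap forward model, classification, decoding, and color-bar sampling."""

import numpy as np
import pytest

from sweclip.colormap import (ColormapSpec, ElasticityScale, PixelClass,
                              blend_over_gray, classify_pixel, decode_pixel,
                              decode_pixels, round_half_away, roundtrip_tolerance,
                              sample_colorbar, value_to_rgb, _blended_index)
from sweclip.synthetic import render_clip

from conftest import TWO_STOP


class TestValueToRgb:
    def test_boundary_stops(self, default_cmap, scale300):
        assert tuple(value_to_rgb(0.0, scale300, default_cmap)) == (0.0, 0.0, 255.0)
        assert tuple(value_to_rgb(300.0, scale300, default_cmap)) == (255.0, 0.0, 0.0)
        # values above e_max clamp to the last stop
        assert tuple(value_to_rgb(450.0, scale300, default_cmap)) == (255.0, 0.0, 0.0)

    def test_midpoint_linear_interpolation(self, scale300):
        rgb = value_to_rgb(150.0, scale300, TWO_STOP)
        assert np.allclose(rgb, (127.5, 0.0, 127.5))

    @pytest.mark.parametrize("bad", [np.nan, np.inf, -1.0])
    def test_invalid_values_error(self, bad, scale300, default_cmap):
        with pytest.raises(ValueError):
            value_to_rgb(bad, scale300, default_cmap)


class TestBlend:
    def test_half_opacity_over_black_and_white(self):
        assert np.allclose(blend_over_gray((255, 0, 0), 0, 0.5), (127.5, 0, 0))
        assert np.allclose(blend_over_gray((255, 0, 0), 255, 0.5), (255, 127.5, 127.5))

    def test_achromatic_closure(self, rng):
        for _ in range(20):
            g = rng.integers(0, 256)
            gray = rng.integers(0, 256)
            alpha = rng.uniform(0.05, 1.0)
            out = blend_over_gray((g, g, g), gray, alpha)
            assert out[0] == out[1] == out[2]

    def test_validates_ranges(self):
        with pytest.raises(ValueError):
            blend_over_gray((300, 0, 0), 0, 0.5)
        with pytest.raises(ValueError):
            blend_over_gray((0, 0, 0), 0, 0.0)


class TestClassify:
    def test_zero_chroma_is_grayscale(self, default_cmap):
        assert classify_pixel((128, 128, 128), default_cmap) is PixelClass.GRAYSCALE

    def test_forward_rendered_pixel_is_colored(self, scale300):
        p = round_half_away(blend_over_gray(value_to_rgb(150.0, scale300, TWO_STOP),
                                            40, 0.5))
        assert tuple(p) == (84.0, 20.0, 84.0)
        assert classify_pixel(p, TWO_STOP) is PixelClass.COLORED

    def test_out_of_gamut_verified_by_enumeration(self, scale300):
        # pure green is far from every achievable blend of a blue->red map
        p = np.array([0.0, 255.0, 0.0])
        flat, _, _ = _blended_index(TWO_STOP, 4)
        brute_min = np.sqrt(((flat - p) ** 2).sum(axis=1)).min()
        assert brute_min > 10
        assert classify_pixel(p, TWO_STOP, gamut_tol=10) is PixelClass.OUT_OF_GAMUT

    def test_nearest_neighbour_matches_brute_force(self, default_cmap, scale300, rng):
        """KD-tree decoding agrees with direct enumeration over the blended set."""
        flat, lut_index, _ = _blended_index(default_cmap, 4)
        pixels = rng.integers(0, 256, size=(50, 3)).astype(float)
        values, labels = decode_pixels(pixels, scale300, default_cmap,
                                       out_of_gamut="nearest")
        for p, v, lab in zip(pixels, values, labels):
            if lab == 0:
                assert np.isnan(v)
                continue
            d2 = ((flat - p) ** 2).sum(axis=1)
            k_brute = lut_index[np.flatnonzero(d2 <= d2.min() + 1e-9)].min()
            assert v == scale300.e_max * k_brute / (default_cmap.n_lut - 1)


class TestDecode:
    def test_grayscale_never_decodes(self, default_cmap, scale300):
        assert decode_pixel((60, 60, 60), scale300, default_cmap) is None

    def test_boundary_roundtrip(self, default_cmap, scale300):
        p = round_half_away(blend_over_gray(value_to_rgb(300.0, scale300, default_cmap),
                                            0, 0.5))
        assert decode_pixel(p, scale300, default_cmap) == 300.0

    def test_roundtrip_within_quantization_bound(self, default_cmap, scale300):
        """Decode error over a value x gray grid stays under the stated bound."""
        v = np.linspace(0.0, 300.0, 61)
        grays = np.arange(0, 256, 15)
        vv, gg = np.meshgrid(v, grays, indexing="ij")
        rendered = round_half_away(
            blend_over_gray(value_to_rgb(vv, scale300, default_cmap), gg, 0.5))
        decoded, _ = decode_pixels(rendered, scale300, default_cmap)
        assert not np.isnan(decoded).any()
        tol = roundtrip_tolerance(scale300, default_cmap)
        assert np.max(np.abs(decoded - vv)) <= tol

    def test_monotone_in_lut_index(self):
        """With no blending, decoding the LUT colors recovers a strictly
        increasing sequence of values along the hue-ordered map."""
        cmap = ColormapSpec(n_lut=64, alpha=1.0)
        scale = ElasticityScale(100.0)
        decoded, _ = decode_pixels(cmap.lut(), scale, cmap)
        assert np.all(np.diff(decoded) > 0)

    def test_tie_breaks_toward_lower_index(self, scale300):
        # a pixel equidistant from two achievable blends takes the lower value
        cmap = ColormapSpec(stops=((0.0, (0, 0, 255)), (1.0, (255, 0, 0))),
                            n_lut=32, alpha=1.0)
        lut = cmap.lut()
        midpoint = (lut[0] + lut[1]) / 2.0
        v = decode_pixel(midpoint, scale300, cmap, gamut_tol=20)
        assert v == 0.0


class TestSampleColorbar:
    def test_recovers_rendered_stops(self, small_config, small_clip):
        frames, _ = small_clip
        recovered = sample_colorbar(frames[0], small_config.colorbar_region,
                                    n_stops=len(small_config.cmap.stops))
        truth = small_config.cmap.colors
        assert np.allclose(recovered.colors, truth, atol=2)
        assert np.allclose(recovered.positions, small_config.cmap.positions)

    def test_uniform_positions_contract(self):
        # a bar rendered from any map yields uniformly spaced stop positions
        bar = np.linspace((255, 0, 0), (0, 0, 255), 100).reshape(100, 1, 3)
        frame = np.tile(bar, (1, 5, 1)).astype(np.uint8)
        spec = sample_colorbar(frame, (0, 100, 0, 5), n_stops=5)
        assert np.allclose(spec.positions, [0, 0.25, 0.5, 0.75, 1.0])

    def test_uniform_bar_errors(self):
        frame = np.full((50, 20, 3), 77, dtype=np.uint8)
        with pytest.raises(ValueError, match="uniform"):
            sample_colorbar(frame, (0, 50, 0, 20))

    def test_bar_outside_frame_errors(self):
        frame = np.zeros((50, 20, 3), dtype=np.uint8)
        with pytest.raises(ValueError, match="outside"):
            sample_colorbar(frame, (0, 60, 0, 20))

    def test_sampled_map_decodes_the_clip(self, small_config, small_clip, scale300):
        """Self-calibration: a colormap recovered from the displayed bar decodes
        the elastogram as well as the generating map."""
        frames, fields = small_clip
        recovered = sample_colorbar(frames[0], small_config.colorbar_region, n_stops=6)
        r0, r1, c0, c1 = small_config.box
        crop = frames[0].pixels[r0:r1, c0:c1]
        decoded, _ = decode_pixels(crop, scale300, recovered)
        truth = fields[0].values
        assert np.nanmax(np.abs(decoded - truth)) <= \
            roundtrip_tolerance(scale300, recovered) + 2 * 300 / recovered.span()


class TestColormapSpec:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ColormapSpec(stops=((0.1, (0, 0, 255)), (1.0, (255, 0, 0))))
        with pytest.raises(ValueError):
            ColormapSpec(stops=((0.0, (0, 0, 255)), (0.5, (0, 255, 0)),
                                (0.4, (255, 255, 0)), (1.0, (255, 0, 0))))
        with pytest.raises(ValueError):
            ColormapSpec(n_lut=16)

    def test_csv_roundtrip(self, tmp_path, default_cmap):
        path = tmp_path / "stops.csv"
        default_cmap.to_csv(path)
        loaded = ColormapSpec.from_csv(path)
        assert loaded.stops == default_cmap.stops
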