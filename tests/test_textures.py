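"""Camouflage texture synthesis: filter, posterisation, palette, edge bands."""

import numpy as np
import pytest
from skimage import color as skcolor

import camosim.textures as tx
from camosim._color import lab_to_srgb8
from camosim.geometry import deg_to_px
from camosim.textures import (
    CamouflageTexture,
    DegenerateTextureError,
    EdgeEnhancementSpec,
    FilterSpec,
    PaletteError,
    PatchPalette,
    apply_edge_enhancement,
    bandpass_gain,
    edge_enhanced_lab,
    make_bandpass_filter,
    make_uniform_texture,
    pick_patch_palette,
    synthesize_two_tone,
)


class TestBandpassFilter:
    def test_unit_gain_at_peak(self, small_filter):
        assert bandpass_gain(small_filter.mu, small_filter) == pytest.approx(1.0)

    def test_half_maximum_at_hwhm(self, small_filter):
        d = small_filter.mu + small_filter.sd_cycles_per_px * np.sqrt(2 * np.log(2))
        assert bandpass_gain(d, small_filter) == pytest.approx(0.5, rel=1e-12)

    def test_radial_symmetry(self, small_filter):
        gain = make_bandpass_filter(small_filter)
        assert np.allclose(gain, gain.T)
        # mirror frequencies have equal radial distance
        assert np.allclose(gain[1:, 1:], gain[1:, 1:][::-1, ::-1])

    def test_invalid_spec_rejected(self):
        for kwargs in [{"mu": 0}, {"sigma": -1}, {"size": 255}, {"size": 0}]:
            with pytest.raises(ValueError):
                FilterSpec(**{"mu": 0.07, "sigma": 120.0, "size": 256, **kwargs})


class TestTwoTone:
    def test_exactly_two_colours_and_even_split(self, small_filter, grey_palette):
        tex = synthesize_two_tone(small_filter, grey_palette, seed=3)
        flat = tex.image.reshape(-1, 3)
        assert len(np.unique(flat, axis=0)) == 2
        frac = tex.label_map.mean()
        assert abs(frac - 0.5) <= 1.0 / small_filter.size

    @pytest.mark.parametrize("seed", range(5))
    def test_label_fraction_half_across_seeds(self, small_filter, grey_palette, seed):
        tex = synthesize_two_tone(small_filter, grey_palette, seed=seed)
        assert tex.label_map.mean() == pytest.approx(0.5, abs=0.01)

    def test_deterministic_under_seed(self, small_filter, grey_palette):
        a = synthesize_two_tone(small_filter, grey_palette, seed=7)
        b = synthesize_two_tone(small_filter, grey_palette, seed=7)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.label_map, b.label_map)

    def test_degenerate_field_raises(self, small_filter, grey_palette, monkeypatch):
        monkeypatch.setattr(
            tx, "filtered_noise_field", lambda spec, rng: np.zeros((8, 8))
        )
        with pytest.raises(DegenerateTextureError):
            synthesize_two_tone(small_filter, grey_palette, seed=0)


@pytest.fixture(scope="module")
def grey_population():
    # greys spanning the full lightness range: L is monotone in grey level
    levels = np.repeat(np.arange(256, dtype=np.uint8), 4)
    return np.stack([levels] * 3, axis=1)


class TestPalette:
    @pytest.mark.parametrize("seed", range(8))
    def test_colours_fall_in_percentile_bands(self, grey_population, seed):
        # brute-force oracle: percentiles of the population's L computed directly
        L = skcolor.rgb2lab(grey_population[None].astype(float) / 255.0)[0, :, 0]
        p35, p45, p55, p65 = np.percentile(L, [35, 45, 55, 65])
        pal = pick_patch_palette(grey_population, seed=seed)
        assert p35 <= pal.L_a <= p45
        assert p55 <= pal.L_b <= p65
        assert pal.L_a < pal.L_b

    def test_identical_population_rejected(self):
        pop = np.full((200, 3), 128, dtype=np.uint8)
        with pytest.raises(PaletteError):
            pick_patch_palette(pop, seed=0)

    def test_tiny_population_rejected(self):
        with pytest.raises(PaletteError):
            pick_patch_palette(np.zeros((10, 3), dtype=np.uint8), seed=0)

    def test_ordering_invariant(self):
        with pytest.raises(PaletteError):
            PatchPalette((10, 10, 10), (20, 20, 20), L_a=50.0, L_b=40.0)


class TestEdgeEnhancement:
    def test_band_offset_is_exact_before_clipping(
        self, straight_boundary_texture, cal
    ):
        ee = EdgeEnhancementSpec(total_width_deg=0.63, offset_L=60.0)
        lab0, lab1, band = edge_enhanced_lab(straight_boundary_texture, ee, cal)
        dL = lab1[..., 0] - lab0[..., 0]
        light = straight_boundary_texture.label_map.astype(bool)
        assert np.allclose(dL[band & light], 60.0)
        assert np.allclose(dL[band & ~light], -60.0)
        assert np.allclose(dL[~band], 0.0)

    def test_band_width_matches_spec(self, straight_boundary_texture, cal):
        ee = EdgeEnhancementSpec(total_width_deg=0.63, offset_L=60.0)
        out = apply_edge_enhancement(straight_boundary_texture, ee, cal)
        changed = np.any(out.image != straight_boundary_texture.image, axis=2)
        widths = changed.sum(axis=1)
        expected = deg_to_px(cal, 0.63)
        assert np.all(np.abs(widths - expected) <= 1.0)
        # the band straddles the boundary symmetrically
        cols = np.flatnonzero(changed[0])
        assert cols[-1] - 127.5 == pytest.approx(127.5 - cols[0], abs=1.0)

    def test_zero_offset_is_identity(self, straight_boundary_texture, cal):
        ee = EdgeEnhancementSpec(total_width_deg=0.63, offset_L=0.0)
        out = apply_edge_enhancement(straight_boundary_texture, ee, cal)
        assert np.array_equal(out.image, straight_boundary_texture.image)

    def test_pixels_outside_band_untouched(self, small_filter, grey_palette, cal):
        tex = synthesize_two_tone(small_filter, grey_palette, seed=5)
        ee = EdgeEnhancementSpec()
        _, _, band = edge_enhanced_lab(tex, ee, cal)
        out = apply_edge_enhancement(tex, ee, cal)
        assert np.array_equal(out.image[~band], tex.image[~band])
        assert out.colouration == "edge_enhanced_disruptive"

    def test_uniform_texture_rejected(self, grey_palette, cal):
        uni = make_uniform_texture(grey_palette, size=64)
        with pytest.raises(ValueError):
            apply_edge_enhancement(uni, EdgeEnhancementSpec(), cal)

    def test_ramp_profile_tapers(self, straight_boundary_texture, cal):
        ee = EdgeEnhancementSpec(total_width_deg=0.63, offset_L=30.0, profile="ramp")
        _, lab1, band = edge_enhanced_lab(straight_boundary_texture, ee, cal)
        lab0 = skcolor.rgb2lab(straight_boundary_texture.image.astype(float) / 255.0)
        dL = np.abs(lab1[..., 0] - lab0[..., 0])[128]
        in_band = np.flatnonzero(band[128])
        # magnitude decreases away from the boundary on the light side
        right = dL[in_band[in_band > 127]]
        assert np.all(np.diff(right) <= 1e-9)


class TestUniformTexture:
    def test_midpoint_lightness(self, grey_palette):
        uni = make_uniform_texture(grey_palette, size=32)
        L = skcolor.rgb2lab(uni.image[:1, :1].astype(float) / 255.0)[0, 0, 0]
        assert L == pytest.approx((grey_palette.L_a + grey_palette.L_b) / 2, abs=0.5)

    def test_single_colour_and_dimensions(self, grey_palette):
        uni = make_uniform_texture(grey_palette, size=48)
        assert uni.image.shape == (48, 48, 3)
        assert len(np.unique(uni.image.reshape(-1, 3), axis=0)) == 1
        assert np.unique(uni.label_map).tolist() == [0]


def test_texture_shape_invariant():
    with pytest.raises(ValueError):
        CamouflageTexture(
            label_map=np.zeros((4, 4), dtype=np.uint8),
            image=np.zeros((5, 4, 3), dtype=np.uint8),
            colouration="uniform",
        )


def test_round_trip_save(tmp_path, small_filter, grey_palette):
    from camosim.textures import save_texture

    tex = synthesize_two_tone(small_filter, grey_palette, seed=1)
    save_texture(tex, tmp_path / "tex.png")
    from PIL import Image

    back = np.asarray(Image.open(tmp_path / "tex.png"))
    assert np.array_equal(back, tex.image)
    assert (tmp_path / "tex.json").exists()
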