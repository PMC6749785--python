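"""Disruptive-camouflage texture synthesis.

Two-tone ("flat disruptive") textures are made by band-pass filtering white
noise in the Fourier domain and posterising the result at its median: pixels
above the median take the lighter patch colour, the rest the darker one. The
radial filter is a Gaussian in radial frequency,

    gain(d) = exp(-(d - mu)^2 / (2 * s^2)),

with ``d`` and the peak ``mu`` in cycles/pixel and the standard deviation
``s = sigma * mu / size`` (i.e. ``sigma * mu`` cycles per image width). With
the defaults mu = 0.07 and sigma = 120 this is a narrow band-pass whose patch
scale is ~14 px at a 1024-px image.

Patch colours are drawn from a natural-colour pixel population: the darker
colour from the 35th-45th CIE L percentile band and the lighter from the
55th-65th band. Edge-enhanced textures additionally lighten the light patches
and darken the dark patches within a band straddling every patch boundary;
the band's total spatial width and the L offset are the two edge-enhancement
parameters. The uniform control is a constant field at the CIELAB midpoint of
the two patch colours, matching the disruptive patterns' mean lightness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from PIL import Image
from scipy import ndimage

from ._color import lab_to_srgb8, srgb8_to_lab
from .geometry import DisplayCalibration, deg_to_px

__all__ = [
    "FilterSpec",
    "PatchPalette",
    "EdgeEnhancementSpec",
    "CamouflageTexture",
    "DegenerateTextureError",
    "PaletteError",
    "bandpass_gain",
    "make_bandpass_filter",
    "synthesize_two_tone",
    "pick_patch_palette",
    "edge_enhanced_lab",
    "apply_edge_enhancement",
    "make_uniform_texture",
    "save_texture",
]

Colouration = Literal["uniform", "flat_disruptive", "edge_enhanced_disruptive"]


class DegenerateTextureError(ValueError):
    """Filtered noise field has no usable variation to posterise."""


class PaletteError(ValueError):
    """Colour population cannot supply the required percentile bands."""


@dataclass(frozen=True)
class FilterSpec:
    """Radial band-pass filter parameters.

    ``mu`` is the peak radial frequency in cycles/pixel; ``sigma`` is the
    dimensionless bandwidth multiplier (the Gaussian s.d. is ``sigma * mu``
    cycles per image); ``size`` is the square image side in pixels.
    """

    mu: float = 0.07
    sigma: float = 120.0
    size: int = 1024

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma <= 0:
            raise ValueError("mu and sigma must be positive")
        if self.size <= 0 or self.size % 2:
            raise ValueError("size must be a positive even integer")

    @property
    def sd_cycles_per_px(self) -> float:
        """Gaussian s.d. expressed in cycles/pixel."""
        return self.sigma * self.mu / self.size


@dataclass(frozen=True)
class PatchPalette:
    """The two patch colours: ``colour_a`` darker, ``colour_b`` lighter."""

    colour_a: tuple[int, int, int]
    colour_b: tuple[int, int, int]
    L_a: float
    L_b: float

    def __post_init__(self) -> None:
        if not self.L_a < self.L_b:
            raise PaletteError("colour_a must be darker than colour_b")


@dataclass(frozen=True)
class EdgeEnhancementSpec:
    """Edge-enhancement band: total spatial width (degrees, both sides of the
    boundary combined) and the CIE L offset applied within it."""

    total_width_deg: float = 0.63
    offset_L: float = 60.0
    profile: Literal["step", "ramp"] = "step"

    def __post_init__(self) -> None:
        if self.total_width_deg <= 0:
            raise ValueError("total_width_deg must be positive")
        if self.offset_L < 0:
            raise ValueError("offset_L must be non-negative")


@dataclass
class CamouflageTexture:
    """A rendered colouration: per-pixel sRGB image plus its patch label map.

    ``label_map`` is 0 for the dark patch, 1 for the light patch; uniform
    textures are all-zero.
    """

    label_map: np.ndarray
    image: np.ndarray
    colouration: Colouration
    palette: PatchPalette | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.label_map.shape:
            raise ValueError("image and label_map dimensions differ")


def bandpass_gain(d: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Gaussian radial gain at radial frequency ``d`` (cycles/pixel)."""
    s = spec.sd_cycles_per_px
    return np.exp(-((np.asarray(d, dtype=np.float64) - spec.mu) ** 2) / (2.0 * s * s))


def make_bandpass_filter(spec: FilterSpec) -> np.ndarray:
    """Radial gain field on the unshifted FFT frequency grid (size x size)."""
    f = np.fft.fftfreq(spec.size)
    d = np.hypot(f[:, None], f[None, :])
    return bandpass_gain(d, spec)


def filtered_noise_field(spec: FilterSpec, rng: np.random.Generator) -> np.ndarray:
    """Band-pass filtered Gaussian white noise (real field, zero-ish mean)."""
    noise = rng.standard_normal((spec.size, spec.size))
    gain = make_bandpass_filter(spec)
    return np.fft.ifft2(np.fft.fft2(noise) * gain).real


def synthesize_two_tone(
    spec: FilterSpec,
    palette: PatchPalette,
    seed: int | np.random.Generator,
) -> CamouflageTexture:
    """Posterise a filtered-noise field at its median into the two patch colours.

    Pixels strictly above the median take ``colour_b`` (light); ties and
    below-median pixels take ``colour_a`` (dark). The split is 50/50 up to
    ties, which have essentially zero measure on the continuous field.
    """
    rng = np.random.default_rng(seed)
    fld = filtered_noise_field(spec, rng)
    if np.ptp(fld) < 1e-12:
        raise DegenerateTextureError("filtered field is constant")
    labels = (fld > np.median(fld)).astype(np.uint8)
    image = np.where(
        labels[..., None].astype(bool),
        np.asarray(palette.colour_b, dtype=np.uint8),
        np.asarray(palette.colour_a, dtype=np.uint8),
    )
    return CamouflageTexture(
        label_map=labels,
        image=image,
        colouration="flat_disruptive",
        palette=palette,
        meta={"filter": {"mu": spec.mu, "sigma": spec.sigma, "size": spec.size}},
    )


def pick_patch_palette(
    colour_population: np.ndarray, seed: int | np.random.Generator
) -> PatchPalette:
    """Draw the dark patch colour from the population's 35th-45th CIE L
    percentile band and the light one from the 55th-65th band.

    ``colour_population`` is an (N, 3) array of 8-bit sRGB pixels with N >= 100
    and a non-degenerate lightness spread.
    """
    pop = np.asarray(colour_population)
    if pop.ndim != 2 or pop.shape[1] != 3 or pop.shape[0] < 100:
        raise PaletteError("population must be (N>=100, 3) sRGB pixels")
    rng = np.random.default_rng(seed)
    L = srgb8_to_lab(pop)[:, 0]
    if np.ptp(L) < 1e-9:
        raise PaletteError("population has degenerate brightness spread")
    p35, p45, p55, p65 = np.percentile(L, [35, 45, 55, 65])
    band_a = np.flatnonzero((L >= p35) & (L <= p45))
    band_b = np.flatnonzero((L >= p55) & (L <= p65))
    if band_a.size == 0 or band_b.size == 0:
        raise PaletteError("empty percentile band")
    ia = rng.choice(band_a)
    ib = rng.choice(band_b)
    if not L[ia] < L[ib]:
        raise PaletteError("percentile bands are not separated in L")
    return PatchPalette(
        colour_a=tuple(int(v) for v in pop[ia]),
        colour_b=tuple(int(v) for v in pop[ib]),
        L_a=float(L[ia]),
        L_b=float(L[ib]),
    )


def _boundary_distance_px(label_map: np.ndarray) -> np.ndarray:
    """Per-pixel Euclidean distance (px) from the pixel centre to the patch
    boundary, taken as half a pixel inside the nearest opposite-label pixel."""
    lab0 = label_map == 0
    d_to_light = ndimage.distance_transform_edt(lab0)
    d_to_dark = ndimage.distance_transform_edt(~lab0)
    return np.where(lab0, d_to_light, d_to_dark) - 0.5


def edge_enhanced_lab(
    texture: CamouflageTexture,
    ee: EdgeEnhancementSpec,
    cal: DisplayCalibration,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIELAB fields before and after edge enhancement, prior to gamut clipping.

    Returns ``(lab_before, lab_after, band_mask)``. Within the band (pixels
    whose boundary distance is at most half the total width), light-patch
    pixels gain ``offset_L`` in L and dark-patch pixels lose it; the "ramp"
    profile tapers the offset linearly from the boundary to the band edge.
    """
    if texture.colouration == "uniform":
        raise ValueError("edge enhancement is undefined for a uniform texture")
    half_px = deg_to_px(cal, ee.total_width_deg) / 2.0
    dist = _boundary_distance_px(texture.label_map)
    band = dist <= half_px
    sign = np.where(texture.label_map == 1, 1.0, -1.0)
    if ee.profile == "ramp":
        mag = ee.offset_L * np.clip(1.0 - dist / half_px, 0.0, 1.0)
    else:
        mag = ee.offset_L
    lab = srgb8_to_lab(texture.image)
    lab_after = lab.copy()
    lab_after[..., 0] = lab[..., 0] + np.where(band, sign * mag, 0.0)
    return lab, lab_after, band


def apply_edge_enhancement(
    texture: CamouflageTexture,
    ee: EdgeEnhancementSpec,
    cal: DisplayCalibration,
) -> CamouflageTexture:
    """Apply the edge-enhancement band and convert back to sRGB with clipping.

    Pixels outside the band are bit-identical to the input; L values pushed
    outside the sRGB gamut are clipped on conversion.
    """
    image = texture.image.copy()
    if ee.offset_L > 0:  # offset 0 is the identity; skip the Lab round-trip
        _, lab_after, band = edge_enhanced_lab(texture, ee, cal)
        image[band] = lab_to_srgb8(lab_after[band])
    return CamouflageTexture(
        label_map=texture.label_map.copy(),
        image=image,
        colouration="edge_enhanced_disruptive",
        palette=texture.palette,
        meta={
            **texture.meta,
            "edge_enhancement": {
                "total_width_deg": ee.total_width_deg,
                "offset_L": ee.offset_L,
                "profile": ee.profile,
            },
        },
    )


def make_uniform_texture(palette: PatchPalette, size: int = 1024) -> CamouflageTexture:
    """Constant-colour control field at the CIELAB midpoint of the palette pair."""
    lab_pair = srgb8_to_lab(
        np.asarray([palette.colour_a, palette.colour_b], dtype=np.uint8)
    )
    mid = lab_to_srgb8(lab_pair.mean(axis=0))
    image = np.broadcast_to(mid, (size, size, 3)).copy()
    return CamouflageTexture(
        label_map=np.zeros((size, size), dtype=np.uint8),
        image=image,
        colouration="uniform",
        palette=palette,
    )


def save_texture(texture: CamouflageTexture, path: Path | str) -> None:
    """Write the texture PNG, its label-map PNG, and a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(texture.image).save(path)
    Image.fromarray(texture.label_map * 255).save(
        path.with_name(path.stem + "_labels.png")
    )
    sidecar = {
        "colouration": texture.colouration,
        "palette": None
        if texture.palette is None
        else {
            "colour_a": list(texture.palette.colour_a),
            "colour_b": list(texture.palette.colour_b),
            "L_a": texture.palette.L_a,
            "L_b": texture.palette.L_b,
        },
        "meta": texture.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
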