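"""Snake-shaped target masks with parametric wiggle amplitude, and scene assembly.

The target silhouette is a procedurally generated snake: a constant-thickness
tube following a sinusoidal centreline over the full body height, with a
rounded head. "Wiggle amplitude" is a multiplier on the silhouette's
horizontal extent — the base mask is horizontally resampled so that the
occupied width equals ``round(amplitude * baseline_width)`` while the vertical
extent is untouched. At amplitude 1.0 the silhouette spans exactly the
baseline width (82 px, ~2.44 degrees by default) and the body is 9.73 degrees
top to bottom.

A stimulus scene places two amplitude-varied snakes side by side on a grey or
leafy background, fills each through its mask from a camouflage texture, and
jitters each snake vertically by an independent uniform offset so that the
two bodies cannot be compared by phase alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .geometry import DisplayCalibration, deg_to_px
from .leaves import LeafBackground
from .textures import CamouflageTexture

__all__ = [
    "SnakeSpec",
    "SnakeMask",
    "StimulusScene",
    "PlacementError",
    "base_snake_mask",
    "make_snake_mask",
    "compose_scene",
]

AMPLITUDE_RANGE = (0.3, 2.5)


class PlacementError(ValueError):
    """Snake placement falls outside the scene canvas."""


@dataclass(frozen=True)
class SnakeSpec:
    """Procedural snake geometry.

    ``baseline_width_px`` is the horizontal extent at amplitude 1.0;
    ``height_deg`` the fixed vertical extent; ``thickness_deg`` the tube
    diameter; ``periods`` the number of sinusoid cycles along the body.
    """

    baseline_width_px: int = 82
    height_deg: float = 9.73
    thickness_deg: float = 0.45
    periods: float = 2.5
    head_scale: float = 1.6
    separation_deg: float = 15.9  # centre-to-centre distance of the two snakes
    y_offset_max_deg: float = 1.49


@dataclass
class SnakeMask:
    mask: np.ndarray  # bool (height, width); occupied bbox is tight
    amplitude: float
    baseline_width: int
    height: int

    @property
    def width(self) -> int:
        return self.mask.shape[1]


@dataclass
class StimulusScene:
    image: np.ndarray
    target_side: Literal["left", "right"]
    target_amplitude: float
    foil_amplitude: float
    y_offsets_deg: dict
    colouration: str
    background: Literal["grey", "leaf"]
    meta: dict = field(default_factory=dict)


@lru_cache(maxsize=8)
def _base_mask_cached(
    baseline_width_px: int,
    height_px: int,
    thickness_px: float,
    periods: float,
    head_scale: float,
) -> np.ndarray:
    r = thickness_px / 2.0
    head_r = head_scale * r
    H = height_px
    amp = (baseline_width_px - thickness_px) / 2.0
    W = int(np.ceil(2 * amp + 2 * r)) + 4
    cx = W / 2.0
    # centreline from just under the head to r above the tail tip
    y = np.linspace(head_r, H - 1 - r, 4 * H)
    x = cx + amp * np.sin(2 * np.pi * periods * (y - y[0]) / (y[-1] - y[0]))
    line = np.ones((H, W), dtype=bool)
    line[np.clip(np.round(y).astype(int), 0, H - 1), np.clip(np.round(x).astype(int), 0, W - 1)] = False
    dist = ndimage.distance_transform_edt(line)
    mask = dist <= r
    # rounded head and tail caps; centres sit half a pixel inside the body so
    # the extreme rows are occupied and the silhouette spans exactly H rows
    yy, xx = np.mgrid[0:H, 0:W]
    mask |= (yy - (head_r - 0.5)) ** 2 + (xx - x[0]) ** 2 <= head_r**2
    mask |= (yy - (H - 1 - r + 0.5)) ** 2 + (xx - x[-1]) ** 2 <= r**2
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def base_snake_mask(spec: SnakeSpec, cal: DisplayCalibration) -> np.ndarray:
    """The amplitude-independent base silhouette, cropped to its bounding box."""
    return _base_mask_cached(
        spec.baseline_width_px,
        int(round(deg_to_px(cal, spec.height_deg))),
        deg_to_px(cal, spec.thickness_deg),
        spec.periods,
        spec.head_scale,
    )


def _resample_width(mask: np.ndarray, new_width: int) -> np.ndarray:
    """Row-wise linear horizontal resampling, re-binarised at 0.5.

    Endpoint-aligned sampling keeps the first and last columns bit-exact, so
    the occupied extent of the result is exactly ``new_width``.
    """
    H, W = mask.shape
    if new_width == W:
        return mask.copy()
    xs = np.linspace(0.0, W - 1.0, new_width)
    x0 = np.clip(np.floor(xs).astype(int), 0, W - 2)
    frac = xs - x0
    vals = mask[:, x0] * (1.0 - frac) + mask[:, x0 + 1] * frac
    return vals > 0.5


def make_snake_mask(
    amplitude: float, cal: DisplayCalibration, spec: SnakeSpec = SnakeSpec()
) -> SnakeMask:
    """Silhouette whose horizontal extent is ``round(amplitude * baseline)``.

    An amplitude of 0.5 halves the baseline width and 2.0 doubles it; the
    vertical extent is identical at every amplitude.
    """
    lo, hi = AMPLITUDE_RANGE
    if not (lo <= amplitude <= hi):
        raise ValueError(f"amplitude must lie in [{lo}, {hi}]")
    base = base_snake_mask(spec, cal)
    target_w = int(round(amplitude * spec.baseline_width_px))
    resampled = _resample_width(
        _resample_width(base, spec.baseline_width_px), target_w
    )
    return SnakeMask(
        mask=resampled,
        amplitude=amplitude,
        baseline_width=spec.baseline_width_px,
        height=base.shape[0],
    )


def _grey_canvas(size: int, grey: tuple[int, int, int]) -> np.ndarray:
    return np.broadcast_to(np.asarray(grey, dtype=np.uint8), (size, size, 3)).copy()


def compose_scene(
    target_amp: float,
    foil_amp: float,
    colouration: str,
    background: Literal["grey", "leaf"],
    cal: DisplayCalibration,
    seed: int | np.random.Generator,
    textures: Sequence[CamouflageTexture],
    leaf_backgrounds: Sequence[LeafBackground] | None = None,
    spec: SnakeSpec = SnakeSpec(),
    size: int = 1024,
    grey: tuple[int, int, int] = (128, 128, 128),
) -> StimulusScene:
    """Compose a two-snake 2AFC scene.

    One texture instance is drawn independently for each snake from
    ``textures`` (and one leafy background from ``leaf_backgrounds`` when
    ``background == "leaf"``); the target is randomly assigned the left or
    right position and each snake gets an independent vertical offset uniform
    in +/- ``spec.y_offset_max_deg``.
    """
    rng = np.random.default_rng(seed)
    if background == "leaf":
        if not leaf_backgrounds:
            raise ValueError("leaf background requested but none supplied")
        bg_idx = int(rng.integers(len(leaf_backgrounds)))
        canvas = leaf_backgrounds[bg_idx].image.copy()
        if canvas.shape[0] != size:
            raise ValueError("background size differs from scene size")
    else:
        bg_idx = -1
        canvas = _grey_canvas(size, grey)

    target_side = "left" if rng.random() < 0.5 else "right"
    sep_px = deg_to_px(cal, spec.separation_deg)
    centres = {"left": size / 2.0 - sep_px / 2.0, "right": size / 2.0 + sep_px / 2.0}
    amps = {
        target_side: target_amp,
        ("right" if target_side == "left" else "left"): foil_amp,
    }
    y_offsets: dict[str, float] = {}
    tex_ids: dict[str, int] = {}
    for side in ("left", "right"):
        y_off_deg = float(rng.uniform(-spec.y_offset_max_deg, spec.y_offset_max_deg))
        y_offsets[side] = y_off_deg
        snake = make_snake_mask(amps[side], cal, spec)
        h, w = snake.mask.shape
        r0 = int(round(size / 2.0 + deg_to_px(cal, abs(y_off_deg)) * np.sign(y_off_deg) - h / 2.0))
        c0 = int(round(centres[side] - w / 2.0))
        if r0 < 0 or c0 < 0 or r0 + h > size or c0 + w > size:
            raise PlacementError("snake placement exceeds the canvas")
        ti = int(rng.integers(len(textures)))
        tex_ids[side] = ti
        tex = textures[ti].image
        if tex.shape[0] < size:
            raise ValueError("texture smaller than the scene")
        region = canvas[r0 : r0 + h, c0 : c0 + w]
        region[snake.mask] = tex[r0 : r0 + h, c0 : c0 + w][snake.mask]
    return StimulusScene(
        image=canvas,
        target_side=target_side,
        target_amplitude=target_amp,
        foil_amplitude=foil_amp,
        y_offsets_deg=y_offsets,
        colouration=colouration,
        background=background,
        meta={"texture_ids": tex_ids, "background_id": bg_idx},
    )
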