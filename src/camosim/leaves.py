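"""Leafy background synthesis with per-leaf cast shadows.

The background is a field of overlapping rotated-ellipse "leaves" drawn
back-to-front at uniform random positions (with torus wrap-around), each
coloured from a naturalistic green/brown CIELAB population. A shadow band is
cast immediately leftward of every leaf by darkening the CIE L channel of the
underlying (non-leaf) pixels by a fixed fraction.

With the default 4,096 leaves of ~0.68 degree mean height on a 1024-px canvas
the leaves alone cover only about two thirds of the area, so the canvas is
first filled with an "understory" colour drawn from the same population; the
realised leaf coverage fraction is recorded in the background's metadata.

Shadows are always computed from the leaf geometry and applied to the
unshadowed render, so re-applying the shadow pass is equivalent to applying
it once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from ._color import lab_to_srgb8, lch_to_srgb8, srgb8_to_lab
from .geometry import DisplayCalibration, deg_to_px

__all__ = [
    "ColourPopulationParams",
    "LeafSpec",
    "LeafRecord",
    "LeafBackground",
    "generate_leaf_background",
    "apply_leaf_shadows",
    "save_background",
]


@dataclass(frozen=True)
class ColourPopulationParams:
    """Parametric CIELAB leaf-colour population (greens/browns).

    Lightness is Normal(L_mean, L_sd) truncated to [L_lo, L_hi]; hue angle and
    chroma are Normal in LCh coordinates. Exact colours are cosmetic; what
    matters downstream is a broad, continuous lightness spread so that the
    patch-palette percentile bands are well populated.
    """

    L_mean: float = 50.0
    L_sd: float = 12.0
    L_lo: float = 20.0
    L_hi: float = 80.0
    hue_mean_deg: float = 120.0
    hue_sd_deg: float = 25.0
    chroma_mean: float = 30.0
    chroma_sd: float = 8.0

    def sample_srgb8(self, n: int, rng: np.random.Generator) -> np.ndarray:
        L = np.clip(rng.normal(self.L_mean, self.L_sd, n), self.L_lo, self.L_hi)
        hue = rng.normal(self.hue_mean_deg, self.hue_sd_deg, n)
        chroma = np.clip(rng.normal(self.chroma_mean, self.chroma_sd, n), 0.0, None)
        return lch_to_srgb8(L, chroma, hue)


@dataclass(frozen=True)
class LeafSpec:
    """Leaf-field parameters.

    ``mean_height_deg`` is the mean vertical extent of a leaf in degrees;
    individual heights are log-normally jittered with relative s.d.
    ``height_jitter``. ``aspect_ratio`` is height/width of the ellipse;
    leaves are rotated uniformly within ``max_rotation_deg`` of vertical.
    ``shadow_fraction`` is the relative CIE L reduction in the shadow band and
    ``shadow_shift_deg`` how far leftward the band is displaced.
    """

    n_leaves: int = 4096
    mean_height_deg: float = 0.68
    height_jitter: float = 0.25
    aspect_ratio: float = 1.6
    max_rotation_deg: float = 15.0
    shadow_fraction: float = 0.30
    shadow_shift_deg: float = 0.15
    colour_population: ColourPopulationParams = field(
        default_factory=ColourPopulationParams
    )

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if not (0 <= self.shadow_fraction < 1):
            raise ValueError("shadow_fraction must lie in [0, 1)")
        if self.mean_height_deg <= 0:
            raise ValueError("mean_height_deg must be positive")


@dataclass(frozen=True)
class LeafRecord:
    """Centre (row, col), realised rasterised height (px) and fill colour."""

    row: float
    col: float
    height_px: int
    colour: tuple[int, int, int]


@dataclass
class LeafBackground:
    image: np.ndarray  # current sRGB render (shadowed if shadows applied)
    base_image: np.ndarray  # unshadowed leaf render
    leaf_mask: np.ndarray  # union of drawn leaf silhouettes
    leaf_records: list[LeafRecord]
    colour_population: np.ndarray  # (N, 3) sRGB pixels of all leaf fill
    meta: dict = field(default_factory=dict)


def _draw_leaf(
    canvas: np.ndarray,
    mask: np.ndarray,
    row: float,
    col: float,
    height_px: float,
    theta_rad: float,
    aspect: float,
    colour: np.ndarray,
) -> int:
    """Paint one rotated ellipse with torus wrap; return its rasterised height."""
    size = canvas.shape[0]
    ct, st = np.cos(theta_rad), np.sin(theta_rad)
    # semi-major axis a (near-vertical) chosen so the rotated vertical extent
    # equals height_px; b = a / aspect
    a = (height_px / 2.0) / np.hypot(ct, st / aspect)
    b = a / aspect
    ey = np.hypot(a * ct, b * st)
    ex = np.hypot(a * st, b * ct)
    dy = np.arange(np.ceil(row - ey), np.floor(row + ey) + 1) - row
    dx = np.arange(np.ceil(col - ex), np.floor(col + ex) + 1) - col
    if dy.size == 0 or dx.size == 0:
        return 0
    u = dx[None, :] * st + dy[:, None] * ct  # along major axis
    v = dx[None, :] * ct - dy[:, None] * st  # along minor axis
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rows_occ = inside.any(axis=1)
    if not rows_occ.any():
        return 0
    rr = ((dy + row).astype(np.intp) % size)[:, None]
    cc = ((dx + col).astype(np.intp) % size)[None, :]
    rr_b = np.broadcast_to(rr, inside.shape)[inside]
    cc_b = np.broadcast_to(cc, inside.shape)[inside]
    canvas[rr_b, cc_b] = colour
    mask[rr_b, cc_b] = True
    occ = np.flatnonzero(rows_occ)
    return int(occ[-1] - occ[0] + 1)


def generate_leaf_background(
    spec: LeafSpec,
    cal: DisplayCalibration,
    seed: int | np.random.Generator,
    size: int = 1024,
) -> LeafBackground:
    """Render ``spec.n_leaves`` leaves at uniform random positions.

    The draw order is random (later leaves occlude earlier ones) and positions
    wrap on a torus so there are no thinned borders. Heights are log-normal
    with mean ``mean_height_deg`` and relative s.d. ``height_jitter``, floored
    at 3 px so that every leaf rasterises.
    """
    rng = np.random.default_rng(seed)
    mean_h = deg_to_px(cal, spec.mean_height_deg)
    j2 = np.log1p(spec.height_jitter**2)
    heights = np.maximum(
        rng.lognormal(np.log(mean_h) - j2 / 2.0, np.sqrt(j2), spec.n_leaves), 3.0
    )
    rows = rng.uniform(0, size, spec.n_leaves)
    cols = rng.uniform(0, size, spec.n_leaves)
    thetas = np.deg2rad(
        rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg, spec.n_leaves)
    )
    colours = spec.colour_population.sample_srgb8(spec.n_leaves, rng)
    understory = spec.colour_population.sample_srgb8(1, rng)[0]

    canvas = np.broadcast_to(understory, (size, size, 3)).copy()
    mask = np.zeros((size, size), dtype=bool)
    records: list[LeafRecord] = []
    for i in range(spec.n_leaves):
        h = _draw_leaf(
            canvas, mask, rows[i], cols[i], heights[i], thetas[i],
            spec.aspect_ratio, colours[i],
        )
        records.append(
            LeafRecord(
                row=float(rows[i]),
                col=float(cols[i]),
                height_px=h,
                colour=tuple(int(v) for v in colours[i]),
            )
        )
    coverage = float(mask.mean())
    meta = {"coverage": coverage, "size": size, "warnings": []}
    if coverage < 1.0:
        meta["warnings"].append(
            f"leaves cover {coverage:.1%} of the canvas; remainder is understory fill"
        )
    return LeafBackground(
        image=canvas.copy(),
        base_image=canvas,
        leaf_mask=mask,
        leaf_records=records,
        colour_population=canvas[mask].astype(np.uint8),
        meta=meta,
    )


def apply_leaf_shadows(
    bg: LeafBackground, spec: LeafSpec, cal: DisplayCalibration
) -> LeafBackground:
    """Darken the band immediately leftward of each leaf by ``shadow_fraction``.

    The band is the union of the leaf silhouettes translated leftward by
    ``shadow_shift_deg`` and clipped to non-leaf pixels; its CIE L channel is
    multiplied by ``1 - shadow_fraction`` (applied in CIELAB on the unshadowed
    render, so the pass is safe to repeat).
    """
    if spec.shadow_fraction == 0:
        return LeafBackground(
            image=bg.base_image.copy(),
            base_image=bg.base_image,
            leaf_mask=bg.leaf_mask,
            leaf_records=bg.leaf_records,
            colour_population=bg.colour_population,
            meta={**bg.meta, "shadow_fraction": 0.0},
        )
    shift = max(1, round(deg_to_px(cal, spec.shadow_shift_deg)))
    shadow = np.roll(bg.leaf_mask, -shift, axis=1) & ~bg.leaf_mask
    image = bg.base_image.copy()
    lab = srgb8_to_lab(image[shadow])
    lab[:, 0] *= 1.0 - spec.shadow_fraction
    image[shadow] = lab_to_srgb8(lab)
    return LeafBackground(
        image=image,
        base_image=bg.base_image,
        leaf_mask=bg.leaf_mask,
        leaf_records=bg.leaf_records,
        colour_population=bg.colour_population,
        meta={
            **bg.meta,
            "shadow_fraction": spec.shadow_fraction,
            "shadow_shift_px": shift,
        },
    )


def save_background(bg: LeafBackground, path: Path | str) -> None:
    """Write the background PNG and a JSON sidecar with per-leaf records."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(bg.image).save(path)
    sidecar = {
        "meta": bg.meta,
        "leaves": [
            {"row": r.row, "col": r.col, "height_px": r.height_px, "colour": list(r.colour)}
            for r in bg.leaf_records
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
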