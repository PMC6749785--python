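"""sRGB <-> CIELAB helpers (D65, 2 degree observer) shared by the stimulus modules."""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color as _skcolor


def srgb8_to_lab(rgb8: np.ndarray) -> np.ndarray:
    """Convert 8-bit sRGB (..., 3) to CIELAB floats."""
    return _skcolor.rgb2lab(np.asarray(rgb8, dtype=np.float64) / 255.0)


def lab_to_srgb8(lab: np.ndarray) -> np.ndarray:
    """Convert CIELAB to 8-bit sRGB, clipping out-of-gamut values."""
    with warnings.catch_warnings():
        # out-of-gamut L values (e.g. edge-enhancement offsets pushing L past
        # 100) are clipped by design; skimage warns about the same clipping
        warnings.filterwarnings("ignore", message=".*clipped.*")
        rgb = _skcolor.lab2rgb(np.asarray(lab, dtype=np.float64))
    return np.round(np.clip(rgb, 0.0, 1.0) * 255.0).astype(np.uint8)


def lch_to_srgb8(L: np.ndarray, chroma: np.ndarray, hue_deg: np.ndarray) -> np.ndarray:
    """Convert CIE LCh (hue in degrees) to 8-bit sRGB with gamut clipping."""
    h = np.deg2rad(np.asarray(hue_deg, dtype=np.float64))
    lab = np.stack(
        [
            np.asarray(L, dtype=np.float64),
            np.asarray(chroma, dtype=np.float64) * np.cos(h),
            np.asarray(chroma, dtype=np.float64) * np.sin(h),
        ],
        axis=-1,
    )
    return lab_to_srgb8(lab)
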