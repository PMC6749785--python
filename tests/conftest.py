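import numpy as np
import pytest

from camosim.geometry import DEFAULT_CALIBRATION
from camosim.textures import FilterSpec, PatchPalette


@pytest.fixture(scope="session")
def cal():
    return DEFAULT_CALIBRATION


@pytest.fixture(scope="session")
def small_filter():
    return FilterSpec(mu=0.07, sigma=120.0, size=256)


@pytest.fixture(scope="session")
def grey_palette():
    """Palette of two greys with known CIE L (darker ~L35, lighter ~L65)."""
    from camosim._color import lab_to_srgb8, srgb8_to_lab

    a = tuple(int(v) for v in lab_to_srgb8(np.array([35.0, 0.0, 0.0])))
    b = tuple(int(v) for v in lab_to_srgb8(np.array([65.0, 0.0, 0.0])))
    La = float(srgb8_to_lab(np.array(a, dtype=np.uint8))[0])
    Lb = float(srgb8_to_lab(np.array(b, dtype=np.uint8))[0])
    return PatchPalette(colour_a=a, colour_b=b, L_a=La, L_b=Lb)


@pytest.fixture(scope="session")
def straight_boundary_texture(grey_palette):
    """Two-tone texture with a single straight vertical patch boundary."""
    from camosim.textures import CamouflageTexture

    size = 256
    labels = np.zeros((size, size), dtype=np.uint8)
    labels[:, size // 2 :] = 1
    image = np.where(
        labels[..., None].astype(bool),
        np.asarray(grey_palette.colour_b, dtype=np.uint8),
        np.asarray(grey_palette.colour_a, dtype=np.uint8),
    )
    return CamouflageTexture(
        label_map=labels, image=image, colouration="flat_disruptive", palette=grey_palette
    )
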