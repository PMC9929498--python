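import numpy as np
import pytest

from minkpat import IntensityImage


def digital_disc(radius: int, pad: int = 5) -> np.ndarray:
    """Boolean disc: pixel centres within `radius` of the centre."""
    n = 2 * (radius + pad)
    yy, xx = np.ogrid[:n, :n]
    c = (n - 1) / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def square_mask(side: int, pad: int = 3) -> np.ndarray:
    n = side + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    m[pad : pad + side, pad : pad + side] = True
    return m


def flood_fill_euler(f: np.ndarray, connectivity: int = 8) -> int:
    """Independent Euler characteristic: label components, label enclosed
    background regions as holes (complementary connectivity)."""
    from scipy import ndimage

    full = np.ones((3, 3))
    cross = ndimage.generate_binary_structure(2, 1)
    fg_struct = full if connectivity == 8 else cross
    bg_struct = cross if connectivity == 8 else full
    _, n_comp = ndimage.label(f, structure=fg_struct)
    bg_lab, n_bg = ndimage.label(~f, structure=bg_struct)
    border = set(np.unique(np.concatenate([
        bg_lab[0, :], bg_lab[-1, :], bg_lab[:, 0], bg_lab[:, -1]
    ])))
    border.discard(0)
    n_holes = n_bg - len(border)
    return n_comp - n_holes


@pytest.fixture
def rng():
    return np.random.default_rng(20230215)


@pytest.fixture
def two_level_image():
    """Background 0, a 10x12 marking block at 1, full-frame mask."""
    px = np.zeros((32, 40))
    px[8:18, 10:22] = 1.0
    return IntensityImage(pixels=px, meta={"inverted": True})
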