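import numpy as np
import pytest
from skimage import draw

from msibreslow.features import MultispectralImage, RoiMask


def disk_mask(radius: float, pad: int = 6) -> RoiMask:
    size = int(2 * radius) + 2 * pad
    grid = np.zeros((size, size), dtype=bool)
    rr, cc = draw.disk((size / 2, size / 2), radius)
    grid[rr, cc] = True
    return RoiMask(grid)


def square_mask(side: int, pad: int = 4) -> RoiMask:
    size = side + 2 * pad
    grid = np.zeros((size, size), dtype=bool)
    grid[pad : pad + side, pad : pad + side] = True
    return RoiMask(grid)


def ellipse_mask(a: float, b: float, pad: int = 6) -> RoiMask:
    """Axis-aligned filled ellipse with semi-axes (a, b), a along columns."""
    size = int(2 * max(a, b)) + 2 * pad
    grid = np.zeros((size, size), dtype=bool)
    rr, cc = draw.ellipse(size / 2, size / 2, b, a)
    grid[rr, cc] = True
    return RoiMask(grid)


def star_mask(radius: float, amplitudes: dict[int, float], size: int = 256) -> RoiMask:
    """Star-convex blob r(theta) = radius * (1 + sum a_k cos(k theta))."""
    thetas = np.linspace(0, 2 * np.pi, 1440, endpoint=False)
    r = radius * (
        1.0 + sum(a * np.cos(k * thetas) for k, a in amplitudes.items())
    )
    rows = size / 2 + r * np.sin(thetas)
    cols = size / 2 + r * np.cos(thetas)
    grid = np.zeros((size, size), dtype=bool)
    rr, cc = draw.polygon(rows, cols, shape=grid.shape)
    grid[rr, cc] = True
    return RoiMask(grid)


def random_blob(rng: np.random.Generator, size: int = 128) -> RoiMask:
    radius = rng.uniform(15, 35)
    ks = (2, 3, 4, 5, 6)
    amps = rng.uniform(0, 0.5, len(ks))
    amps *= rng.uniform(0.05, 0.5) / max(amps.sum(), 1e-9)
    phases = rng.uniform(0, 2 * np.pi, len(ks))
    thetas = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = radius * (
        1.0 + sum(a * np.cos(k * thetas + p) for k, a, p in zip(ks, amps, phases))
    )
    rows = size / 2 + r * np.sin(thetas)
    cols = size / 2 + r * np.cos(thetas)
    grid = np.zeros((size, size), dtype=bool)
    rr, cc = draw.polygon(rows, cols, shape=grid.shape)
    grid[rr, cc] = True
    return RoiMask(grid)


@pytest.fixture
def constant_image():
    """Constant channels (AF=33, G=12, R=80, IR=140) on a 64x64 grid."""
    levels = {"AF": 33, "G": 12, "R": 80, "IR": 140}
    return MultispectralImage(
        {c: np.full((64, 64), v, dtype=np.uint8) for c, v in levels.items()}
    )
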