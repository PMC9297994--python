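"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from sinter4d import phantom as ph
from sinter4d.cli import small_phantom_spec


@pytest.fixture(scope="session")
def small_spec() -> ph.PhantomSpec:
    return small_phantom_spec(seed=12345)


@pytest.fixture(scope="session")
def small_scaffold(small_spec) -> ph.ScaffoldPhantom:
    return ph.generate_scaffold_phantom(small_spec)


@pytest.fixture(scope="session")
def small_sim(small_scaffold) -> ph.SinteringSimulator:
    return ph.SinteringSimulator(small_scaffold, include_noise=True)


@pytest.fixture(scope="session")
def first_time_point(small_sim) -> ph.PhantomTimePoint:
    return small_sim.time_point(0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)


def noisy_disk_slice(
    radius: float = 20.0,
    shape: tuple[int, int] = (64, 64),
    noise_sigma: float = 20.0,
    hole_fraction: float = 0.0,
    seed: int = 0,
    levels: tuple[float, float] = (60.0, 180.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(8-bit slice, truth disk mask) with optional interior holes."""
    rng = np.random.default_rng(seed)
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = shape[0] / 2.0, shape[1] / 2.0
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    fill = disk.copy()
    if hole_fraction > 0:
        holes = rng.random(shape) < hole_fraction
        from scipy import ndimage

        holes = ndimage.binary_dilation(holes & disk, iterations=1)
        interior = ndimage.binary_erosion(disk, iterations=3)
        fill = disk & ~(holes & interior)
    img = np.where(fill, levels[1], levels[0]).astype(float)
    img += noise_sigma * rng.standard_normal(shape)
    return np.clip(img, 0, 255).astype(np.uint8), disk
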