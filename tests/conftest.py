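"""Shared fixtures and small rendering helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from fishratio.config import Config


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


def render_blobs(
    shape: tuple[int, int],
    positions: list[tuple[float, float]],
    sigma_px: float = 1.5,
    amp: float = 250.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render Gaussian blobs on a dark background as an 8-bit raster."""
    img = np.zeros(shape, np.float64)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in positions:
        img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma_px**2))
    if noise_sd > 0:
        img += np.random.default_rng(seed).normal(0, noise_sd, size=shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_disc(shape: tuple[int, int], center: tuple[float, float], radius: float,
                value: int = 220) -> np.ndarray:
    """A hard disc on black background (8-bit)."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, np.uint8)
    img[(yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2] = value
    return img
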