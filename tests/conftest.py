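from dataclasses import replace

import numpy as np
import pytest

from echoseg import (
    BinaryMask,
    GrayImage,
    LevelSetField,
    PhantomConfig,
    generate_phantom,
    generate_suite,
)


@pytest.fixture(scope="session")
def default_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_suite(default_config):
    """The canonical seeded 10-phantom evaluation suite."""
    return generate_suite(default_config, 10, 42)


@pytest.fixture(scope="session")
def noiseless_sample(default_config):
    """Exact piecewise-constant painting (no speckle, no blur)."""
    return generate_phantom(replace(default_config, speckle_scale=0.0, blur_sd=0.0))


@pytest.fixture(scope="session")
def default_sample(default_config):
    return generate_phantom(replace(default_config, seed=7))


@pytest.fixture
def disc_mask():
    """Pixel disc of radius 20 centered in a 128x128 grid."""
    rr, cc = np.mgrid[0:128, 0:128]
    return BinaryMask(np.hypot(rr - 64, cc - 64) <= 20)


@pytest.fixture
def ramp_image():
    rr, cc = np.mgrid[0:64, 0:64]
    return GrayImage(((rr + cc) * 2).clip(0, 255).astype(np.uint8))


def analytic_disc_field(radius: float, size: int = 128, center=(64.0, 64.0)):
    """Exact signed distance to a circle: phi = |p - c| - r."""
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    return LevelSetField(np.hypot(rr - center[0], cc - center[1]) - radius)


def zero_set_mean_radius(field, center=(64.0, 64.0)):
    """Mean vertex distance to ``center`` of the longest closed contour."""
    from echoseg import extract_zero_level

    contours = [c for c in extract_zero_level(field) if c.closed]
    v = max(contours, key=lambda c: len(c.vertices)).vertices
    return float(np.hypot(v[:, 0] - center[0], v[:, 1] - center[1]).mean())
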