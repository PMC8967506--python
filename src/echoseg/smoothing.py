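"""Gaussian template construction and image smoothing.

Speckle makes neighbouring ultrasound pixels fluctuate strongly, so the
pipeline first replaces each pixel by a Gaussian-weighted average of its
(2r+1) x (2r+1) neighbourhood. The template weights follow the isotropic
2-D Gaussian density H(a,b) = exp(-(a^2+b^2) / (2 lambda^2)) / (2 pi
lambda^2), which depends on the offset only through a^2 + b^2 (circular
level lines). Kernels are normalized to unit sum by default so convolution
is a convex combination: it preserves constants and never widens the
intensity range.

Numerical choices: the template half-width defaults to r = ceil(3 lambda)
(covering > 99.7 % of the mass), borders are mirrored without repeating the
edge pixel, and outputs are rounded half-up and clipped to [0, 255].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import GrayImage

__all__ = ["GaussianKernel", "gaussian_density_1d", "build_kernel", "convolve"]


@dataclass(frozen=True)
class GaussianKernel:
    """A (2r+1) x (2r+1) grid of Gaussian template weights."""

    weights: np.ndarray
    lambda_sd: float
    radius: int
    normalized: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        n = 2 * self.radius + 1
        if w.shape != (n, n):
            raise ParameterError(f"kernel shape {w.shape} != ({n}, {n})")
        if (w < 0).any():
            raise ParameterError("kernel weights must be non-negative")
        if self.normalized and abs(w.sum() - 1.0) > 1e-12:
            raise ParameterError("normalized kernel must sum to 1")
        object.__setattr__(self, "weights", w)


def gaussian_density_1d(a: float, epsilon: float = 0.0, sd: float = 1.0) -> float:
    """Gaussian density (1/(sd sqrt(2 pi))) exp(-(a-eps)^2 / (2 sd^2))."""
    if sd <= 0:
        raise ParameterError(f"standard deviation must be positive, got {sd}")
    return math.exp(-((a - epsilon) ** 2) / (2.0 * sd * sd)) / (sd * math.sqrt(2 * math.pi))


def build_kernel(
    lambda_sd: float, radius: int | None = None, normalize: bool = True
) -> GaussianKernel:
    """Sample the 2-D Gaussian density on a centered square template.

    The weight at offset (a, b) is proportional to
    exp(-(a^2+b^2)/(2 lambda^2)) / (2 pi lambda^2); with ``normalize`` the
    weights are divided by their sum. ``radius`` defaults to ceil(3 lambda).
    """
    if lambda_sd <= 0:
        raise ParameterError(f"lambda_sd must be positive, got {lambda_sd}")
    if radius is None:
        radius = math.ceil(3 * lambda_sd)
    if radius < 1:
        raise ParameterError(f"radius must be >= 1, got {radius}")
    offs = np.arange(-radius, radius + 1, dtype=np.float64)
    r2 = offs[:, None] ** 2 + offs[None, :] ** 2
    w = np.exp(-r2 / (2.0 * lambda_sd**2)) / (2.0 * math.pi * lambda_sd**2)
    if normalize:
        w = w / w.sum()
    return GaussianKernel(w, lambda_sd=lambda_sd, radius=radius, normalized=normalize)


def convolve(image: GrayImage, kernel: GaussianKernel) -> GrayImage:
    """Smooth an image with a normalized Gaussian template.

    Each output pixel is the kernel-weighted sum over its neighbourhood;
    borders are mirror-reflected (edge pixel not repeated). The result is
    rounded half-up and clipped to [0, 255].
    """
    if not kernel.normalized:
        raise ParameterError("convolve requires a normalized kernel")
    out = ndimage.correlate(
        image.pixels.astype(np.float64), kernel.weights, mode="mirror"
    )
    return GrayImage(np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8))
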