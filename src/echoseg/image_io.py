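"""Grayscale image and binary mask I/O.

The pipeline operates on 2-D 8-bit intensity rasters. This module reads and
writes them as single-channel PNG or TIFF and carries them in two small
container types, :class:`GrayImage` and :class:`BinaryMask`.

Conventions (inherited by every other module):

* coordinates are (row, col), 0-based, origin at the top-left;
* masks serialize as 8-bit PNG with 0 = background, 255 = foreground, and
  any nonzero value reads back as foreground;
* images deeper than 8 bits are linearly rescaled on read so their maximum
  maps to 255, because the histogram machinery is defined on 256 bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError

__all__ = [
    "GrayImage",
    "BinaryMask",
    "read_gray_image",
    "write_gray_image",
    "read_mask",
    "write_mask",
]

# ITU-R BT.601 luma weights for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayImage:
    """A 2-D 8-bit intensity raster.

    Every intensity lies in [0, 255]; the pixel array is stored as uint8.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D intensity grid, got ndim={px.ndim}")
        if px.size == 0:
            raise InputError("zero-sized image")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise InputError("intensities outside [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean grid annotating an image of the same shape."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D mask, got ndim={px.ndim}")
        if px.size == 0:
            raise InputError("zero-sized mask")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) array to a 2-D float gray array."""
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0].astype(np.float64)
        if arr.shape[2] in (3, 4):
            # Drop alpha if present, weight by BT.601 luma.
            return arr[:, :, :3].astype(np.float64) @ _LUMA
        raise InputError(f"unsupported channel count {arr.shape[2]}")
    if arr.ndim == 2:
        return arr.astype(np.float64)
    raise InputError(f"unsupported image dimensionality {arr.ndim}")


def read_gray_image(path: str | Path) -> GrayImage:
    """Read a PNG or TIFF as a :class:`GrayImage`.

    RGB input is converted with the BT.601 luma weights and rounded to the
    nearest integer. Inputs deeper than 8 bits are rescaled so their maximum
    value maps to 255 (a warning is emitted, not an error).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise InputError(f"cannot read image {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-sized image: {path}")
    gray = _to_gray(arr)
    if gray.max() > 255:
        warnings.warn(
            f"{path.name}: bit depth exceeds 8 bits; rescaling max "
            f"{gray.max():g} -> 255",
            stacklevel=2,
        )
        gray = gray * (255.0 / gray.max())
    return GrayImage(np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8))


def write_gray_image(image: GrayImage, path: str | Path) -> None:
    """Write a :class:`GrayImage` as 8-bit single-channel PNG or TIFF.

    The file round-trips through :func:`read_gray_image` bit-exactly.
    Raises :class:`OSError` if the parent directory does not exist.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise OSError(f"parent directory does not exist: {path.parent}")
    iio.imwrite(path, image.pixels)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask PNG; any nonzero pixel is foreground."""
    return BinaryMask(read_gray_image(path).pixels > 0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 8-bit PNG, 0 = background, 255 = foreground."""
    write_gray_image(GrayImage(mask.pixels.astype(np.uint8) * 255), path)
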