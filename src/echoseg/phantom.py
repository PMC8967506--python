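"""Seeded synthetic echocardiogram phantoms with known ground truth.

B-mode cardiac ultrasound shows the blood-filled chamber cavity as a dark
ellipse surrounded by brighter myocardium, inside a fan-shaped imaging
sector, all corrupted by speckle. The generator emulates exactly those
features: it paints a piecewise-constant scene (background 5, sector at
``myocardium_mean``, cavity ellipse at ``cavity_mean``), multiplies each
pixel by a unit-mean gamma speckle draw (shape 1/s^2, scale s^2, the
standard fully-developed-speckle surrogate with relative standard deviation
s), smooths with the Gaussian template module to mimic the system PSF, and
clips to [0, 255]. The cavity ellipse interior is returned as the exact
ground-truth mask.

Everything is deterministic given the config seed; suites derive per-sample
subseeds by counter from the base seed.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError
from .image_io import BinaryMask, GrayImage, write_gray_image, write_mask
from .smoothing import build_kernel, convolve

__all__ = [
    "PhantomConfig",
    "PhantomSample",
    "sector_mask",
    "ellipse_mask",
    "generate_phantom",
    "generate_suite",
    "load_config",
    "save_config",
    "write_suite",
]

_BACKGROUND_GRAY = 5.0


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast, and noise settings for one phantom.

    Defaults describe a mid-ventricular short-axis-like frame on a 128 px
    grid: a 22 x 16 px semi-axis cavity at gray 30 inside myocardium at
    gray 180, 20 % multiplicative speckle, and a 0.5 px PSF blur.
    """

    size: int = 128
    cavity_center: tuple[float, float] = (70.0, 64.0)
    cavity_axes: tuple[float, float] = (22.0, 16.0)
    cavity_rotation: float = 0.0
    cavity_mean: float = 30.0
    myocardium_mean: float = 180.0
    wall_thickness: float = 6.0
    speckle_scale: float = 0.2
    blur_sd: float = 0.5
    sector_angle: float = 75.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ParameterError("phantom size must be >= 32 px")
        if not (0 <= self.cavity_mean <= 255 and 0 <= self.myocardium_mean <= 255):
            raise ParameterError("gray means must lie in [0, 255]")
        if self.cavity_mean >= self.myocardium_mean:
            raise ParameterError("cavity must be darker than myocardium")
        if min(self.cavity_axes) <= 0 or self.wall_thickness < 0:
            raise ParameterError("axes must be positive, wall thickness >= 0")
        if self.speckle_scale < 0 or self.blur_sd < 0:
            raise ParameterError("noise scales must be >= 0")
        if not (10 <= self.sector_angle <= 180):
            raise ParameterError("sector angle must lie in [10, 180] degrees")
        # The cavity plus its wall margin must fit inside the imaging sector.
        sector = sector_mask(self.size, self.sector_angle)
        a, b = self.cavity_axes
        padded = ellipse_mask(
            self.size,
            self.cavity_center,
            (a + self.wall_thickness, b + self.wall_thickness),
            self.cavity_rotation,
        )
        if (padded.pixels & ~sector.pixels).any():
            raise ParameterError("cavity ellipse plus wall does not fit in the sector")


@dataclass(frozen=True)
class PhantomSample:
    """A synthetic frame, its exact cavity mask, and its generating config."""

    image: GrayImage
    truth_mask: BinaryMask
    config: PhantomConfig
    sector: BinaryMask = field(repr=False, default=None)  # type: ignore[assignment]


def sector_mask(size: int, angle_deg: float, max_depth_frac: float = 0.98) -> BinaryMask:
    """The imaging cone: apex at the top-center, opening downward."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rr  # depth below the apex (row 0)
    dc = cc - (size - 1) / 2.0
    depth = np.hypot(dr, dc)
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arctan2(np.abs(dc), dr))
    inside = (theta <= angle_deg / 2.0) & (depth <= max_depth_frac * size) & (dr > 0)
    return BinaryMask(inside)


def ellipse_mask(
    size: int,
    center: tuple[float, float],
    axes: tuple[float, float],
    rotation_deg: float = 0.0,
) -> BinaryMask:
    """Pixels whose centers fall strictly inside a rotated ellipse.

    ``axes`` are the semi-axes along the (row, col) directions before
    rotation; ``rotation_deg`` rotates the ellipse counterclockwise in the
    (col, row) plane.
    """
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rr - center[0]
    dc = cc - center[1]
    th = math.radians(rotation_deg)
    ur = dr * math.cos(th) + dc * math.sin(th)
    uc = -dr * math.sin(th) + dc * math.cos(th)
    a, b = axes
    return BinaryMask((ur / a) ** 2 + (uc / b) ** 2 < 1.0)


def generate_phantom(config: PhantomConfig) -> PhantomSample:
    """Render one phantom deterministically from its config.

    Stages: piecewise-constant painting, unit-mean gamma speckle,
    Gaussian-template blur, clip to [0, 255].
    """
    rng = np.random.default_rng(config.seed)
    sector = sector_mask(config.size, config.sector_angle)
    cavity = ellipse_mask(
        config.size, config.cavity_center, config.cavity_axes, config.cavity_rotation
    )
    img = np.full((config.size, config.size), _BACKGROUND_GRAY)
    img[sector.pixels] = config.myocardium_mean
    img[cavity.pixels] = config.cavity_mean
    if config.speckle_scale > 0:
        s2 = config.speckle_scale**2
        img = img * rng.gamma(shape=1.0 / s2, scale=s2, size=img.shape)
    image = GrayImage(np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8))
    if config.blur_sd > 0:
        image = convolve(image, build_kernel(config.blur_sd))
    return PhantomSample(image=image, truth_mask=cavity, config=config, sector=sector)


def _subseed(seed: int, counter: int) -> int:
    """Deterministic per-sample seed derived from (seed, counter)."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(counter,))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_suite(
    base_config: PhantomConfig, n: int, seed: int
) -> list[PhantomSample]:
    """Generate ``n`` phantoms with jittered cavity geometry.

    Semi-axes are jittered uniformly by +-20 % and the rotation drawn
    uniformly on [0, 180) degrees; all jitter flows from one generator
    seeded with ``seed`` and each sample renders under a counter-derived
    subseed, so the suite is fully reproducible.
    """
    if n < 1:
        raise ParameterError("suite size must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        a, b = base_config.cavity_axes
        jitter = rng.uniform(0.8, 1.2, size=2)
        rotation = float(rng.uniform(0.0, 180.0))
        cfg = replace(
            base_config,
            cavity_axes=(a * jitter[0], b * jitter[1]),
            cavity_rotation=rotation,
            seed=_subseed(seed, i),
        )
        samples.append(generate_phantom(cfg))
    return samples


def _config_hash(config: PhantomConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> PhantomConfig:
    """Load a :class:`PhantomConfig` from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"phantom config must be a mapping: {path}")
    known = PhantomConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ParameterError(f"unknown phantom config keys: {sorted(unknown)}")
    for key in ("cavity_center", "cavity_axes"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomConfig(**raw)


def save_config(config: PhantomConfig, path: str | Path) -> None:
    data = asdict(config)
    data["cavity_center"] = list(data["cavity_center"])
    data["cavity_axes"] = list(data["cavity_axes"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def write_suite(samples: list[PhantomSample], out_dir: str | Path) -> Path:
    """Write image/mask PNG pairs plus a manifest CSV; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "seed", "config_hash", "image", "mask", "sector"])
        for i, sample in enumerate(samples):
            img_name = f"phantom_{i:03d}.png"
            mask_name = f"phantom_{i:03d}_mask.png"
            sector_name = f"phantom_{i:03d}_sector.png"
            write_gray_image(sample.image, out / img_name)
            write_mask(sample.truth_mask, out / mask_name)
            write_mask(sample.sector, out / sector_name)
            writer.writerow(
                [
                    i,
                    sample.config.seed,
                    _config_hash(sample.config),
                    img_name,
                    mask_name,
                    sector_name,
                ]
            )
    return manifest
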