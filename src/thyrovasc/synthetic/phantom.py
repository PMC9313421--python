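"""Doppler-like image phantoms with exactly known regional colour coverage.

Each phantom is an 8-bit RGB frame: a greyscale (R = G = B) background —
flat or speckled — carrying a nodule ROI in which colour "flow" primitives
(small disks) are painted. Primitives are clipped to their target region
(peripheral rim or central core of the ROI at the configured offset) and
the exact set of painted pixels is recorded, so the per-region colour-pixel
counts used as ground truth are exact by construction, not estimated.

Painting continues until the requested coverage fraction is met; the last
primitive may overshoot it, so achieved coverage equals or slightly exceeds
the target. Painted colours have chroma >= 100, far above the default
detection threshold of 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw

from ..segmentation import RegionPartition, partition_regions

__all__ = ["ImagePhantomSpec", "PhantomGroundTruth", "generate_doppler_image", "make_roi_mask"]

_ROI_SHAPES = ("circle", "ellipse", "blob")
_PALETTES = ("red_blue", "orange")
_NOISES = ("flat", "speckle")


@dataclass(frozen=True)
class ImagePhantomSpec:
    """Recipe for one synthetic Doppler frame.

    ``roi_params`` are in pixels, centred on the frame by default:
    circle ``{"radius": r}``; ellipse ``{"r_radius": a, "c_radius": b}``;
    blob ``{"radius": r, "wobble": w}`` — a circle whose radius is
    modulated by low-order harmonics of relative amplitude ``w``.
    """

    width: int = 256
    height: int = 256
    roi_shape: str = "circle"
    roi_params: dict = field(default_factory=lambda: {"radius": 80})
    target_coverage_peripheral: float = 0.2
    target_coverage_central: float = 0.2
    offset_fraction: float = 0.22
    colour_palette: str = "red_blue"
    background_noise: str = "speckle"
    primitive_radius: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("target_coverage_peripheral", "target_coverage_central"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.roi_shape not in _ROI_SHAPES:
            raise ValueError(f"unknown roi_shape {self.roi_shape!r}")
        if self.colour_palette not in _PALETTES:
            raise ValueError(f"unknown colour_palette {self.colour_palette!r}")
        if self.background_noise not in _NOISES:
            raise ValueError(f"unknown background_noise {self.background_noise!r}")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Exact painted-pixel record of one phantom."""

    colour_mask: np.ndarray
    count_peripheral: int
    count_central: int
    area_peripheral: int
    area_central: int
    partition: RegionPartition

    @property
    def vi_peripheral(self) -> float:
        return 100.0 * self.count_peripheral / self.area_peripheral

    @property
    def vi_central(self) -> float:
        return 100.0 * self.count_central / self.area_central


def make_roi_mask(spec: ImagePhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterise the ROI shape; reject shapes that do not fit the frame."""
    h, w = spec.height, spec.width
    cr, cc = h / 2.0, w / 2.0
    mask = np.zeros((h, w), dtype=bool)
    if spec.roi_shape == "circle":
        radius = spec.roi_params["radius"]
        _check_fits(radius, min(h, w), "radius")
        rr, cc_idx = draw.disk((cr, cc), radius, shape=(h, w))
    elif spec.roi_shape == "ellipse":
        a = spec.roi_params["r_radius"]
        b = spec.roi_params["c_radius"]
        _check_fits(a, h, "r_radius")
        _check_fits(b, w, "c_radius")
        rr, cc_idx = draw.ellipse(cr, cc, a, b, shape=(h, w))
    else:  # blob
        radius = spec.roi_params["radius"]
        wobble = spec.roi_params.get("wobble", 0.15)
        _check_fits(radius * (1 + wobble), min(h, w), "radius")
        theta = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        r_mod = np.ones_like(theta)
        for harmonic in (2, 3, 5):
            r_mod += wobble / harmonic * np.sin(
                harmonic * theta + rng.uniform(0, 2 * np.pi)
            )
        radii = radius * r_mod
        rr, cc_idx = draw.polygon(
            cr + radii * np.sin(theta), cc + radii * np.cos(theta), shape=(h, w)
        )
    mask[rr, cc_idx] = True
    return mask


def _check_fits(extent: float, frame_extent: int, param: str) -> None:
    if 2 * extent >= frame_extent:
        raise ValueError(
            f"ROI does not fit the frame: {param}={extent} requires a frame "
            f"dimension larger than {2 * extent}"
        )


def _background(spec: ImagePhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.background_noise == "flat":
        grey = np.full((h, w), 90, dtype=np.uint8)
    else:
        # multiplicative speckle on a smooth base, the classic B-mode look
        base = 60.0 + 50.0 * ndimage.gaussian_filter(rng.standard_normal((h, w)), 12)
        speckle = rng.rayleigh(scale=1.0, size=(h, w)) / np.sqrt(np.pi / 2)
        grey = np.clip(base * speckle, 0, 255).astype(np.uint8)
    return np.repeat(grey[:, :, None], 3, axis=2)


def _primitive_colour(palette: str, rng: np.random.Generator) -> np.ndarray:
    if palette == "red_blue":
        strong = rng.integers(160, 256)
        weak = rng.integers(0, 60)
        if rng.random() < 0.5:
            return np.array([strong, weak, weak], dtype=np.uint8)  # red: toward probe
        return np.array([weak, weak, strong], dtype=np.uint8)  # blue: away
    # orange power-Doppler map
    r = rng.integers(200, 256)
    g = rng.integers(90, 150)
    return np.array([r, g, 20], dtype=np.uint8)


def _paint_region(
    image: np.ndarray,
    region: np.ndarray,
    target_coverage: float,
    primitive_radius: int,
    palette: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Paint colour primitives into ``region`` until coverage is reached."""
    painted = np.zeros(region.shape, dtype=bool)
    area = int(region.sum())
    target = target_coverage * area
    if target <= 0:
        return painted
    region_rows, region_cols = np.nonzero(region)
    while painted.sum() < target:
        unpainted = region & ~painted
        idx = rng.integers(len(region_rows))
        centre = (region_rows[idx], region_cols[idx])
        radius = rng.integers(1, primitive_radius + 1)
        rr, cc = draw.disk(centre, radius, shape=region.shape)
        keep = region[rr, cc] & ~painted[rr, cc]
        if not keep.any():
            # near saturation a uniform draw may add nothing; take a fresh
            # pixel from the unpainted remainder to guarantee progress
            ur, uc = np.nonzero(unpainted)
            j = rng.integers(len(ur))
            rr, cc = draw.disk((ur[j], uc[j]), radius, shape=region.shape)
            keep = region[rr, cc] & ~painted[rr, cc]
        rr, cc = rr[keep], cc[keep]
        painted[rr, cc] = True
        image[rr, cc] = _primitive_colour(palette, rng)
    return painted


def generate_doppler_image(
    spec: ImagePhantomSpec,
) -> tuple[np.ndarray, np.ndarray, PhantomGroundTruth]:
    """Generate one phantom frame.

    Returns the RGB image, the ROI mask, and the exact ground truth
    (painted colour mask, per-region counts and areas, and the partition
    used for painting). Identical spec (including seed) gives bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    roi = make_roi_mask(spec, rng)
    image = _background(spec, rng)
    part = partition_regions(roi, spec.offset_fraction)

    painted_p = _paint_region(
        image, part.peripheral_mask, spec.target_coverage_peripheral,
        spec.primitive_radius, spec.colour_palette, rng,
    )
    painted_c = _paint_region(
        image, part.central_mask, spec.target_coverage_central,
        spec.primitive_radius, spec.colour_palette, rng,
    )
    truth = PhantomGroundTruth(
        colour_mask=painted_p | painted_c,
        count_peripheral=int(painted_p.sum()),
        count_central=int(painted_c.sum()),
        area_peripheral=int(part.peripheral_mask.sum()),
        area_central=int(part.central_mask.sum()),
        partition=part,
    )
    return image, roi, truth
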