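"""Cell volume from fluorescence-exclusion images and microchannel lengths.

In a fluorescence-exclusion chamber of height ``h_max`` filled with a
non-entering fluorescent probe, the intensity at a pixel is proportional to
the free height of the chamber above that pixel: an object of height h
excludes fluorescence, so ``I = I_max - alpha_cal * h`` with
``alpha_cal = (I_max - I_min) / h_max`` calibrated from the empty roof
(I_max) and full-height pillars (I_min). Summing the per-pixel height
deficit over the cell mask gives the cell volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExclusionImage",
    "Calibration",
    "MicrochannelGeometry",
    "calibrate",
    "integrate_volume",
    "microchannel_volume",
    "render_synthetic_chamber",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]


@dataclass
class ExclusionImage:
    """Single-channel exclusion image with its physical metadata."""

    pixels: np.ndarray  # intensity, arbitrary units, >= 0
    pixel_size: float  # µm per pixel side
    chamber_height: float  # µm

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.chamber_height <= 0:
            raise ValueError("chamber_height must be > 0")


@dataclass
class Calibration:
    """Intensity-to-height calibration of one exclusion image."""

    I_max: float  # background intensity, no object
    I_min: float  # intensity under a full-height pillar
    chamber_height: float  # µm

    def __post_init__(self) -> None:
        if not self.I_max > self.I_min >= 0:
            raise ValueError(
                f"need I_max > I_min >= 0, got I_max={self.I_max}, I_min={self.I_min}"
            )

    @property
    def alpha_cal(self) -> float:
        """Intensity per µm of excluded height."""
        return (self.I_max - self.I_min) / self.chamber_height


@dataclass(frozen=True)
class MicrochannelGeometry:
    """Rectangular microchannel cross-section."""

    width: float  # µm
    height: float  # µm

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("channel width and height must be > 0")

    @property
    def cross_section(self) -> float:
        """Cross-section area in µm²."""
        return self.width * self.height


def calibrate(
    image: ExclusionImage,
    roof_mask: np.ndarray,
    pillar_mask: np.ndarray,
) -> Calibration:
    """Per-image calibration from the empty roof and full-height pillars."""
    roof_mask = np.asarray(roof_mask, dtype=bool)
    pillar_mask = np.asarray(pillar_mask, dtype=bool)
    if not roof_mask.any() or not pillar_mask.any():
        raise ValueError("roof and pillar masks must be non-empty")
    if np.any(roof_mask & pillar_mask):
        raise ValueError("roof and pillar masks must be disjoint")
    I_max = float(image.pixels[roof_mask].mean())
    I_min = float(image.pixels[pillar_mask].mean())
    if I_max <= I_min:
        raise ValueError(
            "calibration failure: roof intensity not above pillar intensity "
            "(inverted chamber or saturation?)"
        )
    return Calibration(I_max=I_max, I_min=I_min, chamber_height=image.chamber_height)


def integrate_volume(
    image: ExclusionImage,
    cell_mask: np.ndarray,
    cal: Calibration,
    pillar_mask: np.ndarray | None = None,
    clip_warn_fraction: float = 0.01,
) -> tuple[float, int]:
    """Integrate the fluorescence deficit over a cell mask.

    V = sum over the mask of (I_max - I) / alpha_cal * pixel_size².
    Negative per-pixel heights (noise above background) are clipped to zero
    and counted; a warning is emitted when more than ``clip_warn_fraction``
    of mask pixels were clipped. Returns ``(volume_um3, n_clipped)``.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.pixels.shape:
        raise ValueError("cell mask shape does not match the image")
    if pillar_mask is not None and np.any(cell_mask & np.asarray(pillar_mask, bool)):
        raise ValueError("cell mask overlaps a pillar")
    if not cell_mask.any():
        return 0.0, 0
    heights = (cal.I_max - image.pixels[cell_mask]) / cal.alpha_cal
    n_clipped = int((heights < 0).sum())
    if n_clipped > clip_warn_fraction * cell_mask.sum():
        warnings.warn(
            f"{n_clipped} of {int(cell_mask.sum())} mask pixels had negative "
            "height (clipped to 0)",
            stacklevel=2,
        )
    volume = float(np.clip(heights, 0, None).sum() * image.pixel_size**2)
    return volume, n_clipped


def microchannel_volume(length: float, geom: MicrochannelGeometry) -> float:
    """Volume of a cylinder-shaped confined cell: length x cross-section."""
    if length <= 0:
        raise ValueError("cell length must be > 0")
    return length * geom.cross_section


def render_synthetic_chamber(
    cell_height_maps: list[np.ndarray],
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
    chamber_height: float = 20.0,
    I_max: float = 2000.0,
    alpha_cal: float = 50.0,
    pillar_size: int = 12,
    noise_cv: float = 0.0,
    seed: int | None = None,
):
    """Render an exclusion image with known geometry for testing.

    ``cell_height_maps`` are full-frame arrays of heights (µm, zero outside
    the cell); pillars of full chamber height are placed in the four image
    corners. Returns ``(image, masks, true_volumes)`` where ``masks`` holds
    the roof/pillar masks and one boolean mask per cell, and the true volume
    of each cell is the sum of its height map times the pixel area.
    """
    h = np.zeros(shape, dtype=float)
    cell_masks = []
    for hm in cell_height_maps:
        hm = np.asarray(hm, dtype=float)
        if hm.shape != tuple(shape):
            raise ValueError("cell height maps must match the image shape")
        if np.any(hm > chamber_height):
            raise ValueError("cell taller than the chamber")
        if np.any(hm < 0):
            raise ValueError("heights must be >= 0")
        h += hm
        cell_masks.append(hm > 0)
    if np.any(h > chamber_height):
        raise ValueError("overlapping cells exceed the chamber height")

    pillar_mask = np.zeros(shape, dtype=bool)
    p = pillar_size
    pillar_mask[:p, :p] = pillar_mask[:p, -p:] = True
    pillar_mask[-p:, :p] = pillar_mask[-p:, -p:] = True
    if any(np.any(pillar_mask & cm) for cm in cell_masks):
        raise ValueError("a cell overlaps a pillar")
    h[pillar_mask] = chamber_height

    pixels = I_max - alpha_cal * h
    if np.any(pixels < 0):
        raise ValueError("alpha_cal * chamber_height exceeds I_max")
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels * (1.0 + noise_cv * rng.standard_normal(shape))
        pixels = np.clip(pixels, 0, None)
    roof_mask = ~pillar_mask & (h == 0)
    image = ExclusionImage(
        pixels=pixels, pixel_size=pixel_size, chamber_height=chamber_height
    )
    masks = {"roof": roof_mask, "pillar": pillar_mask, "cells": cell_masks}
    true_volumes = [
        float(np.asarray(hm, dtype=float).sum() * pixel_size**2)
        for hm in cell_height_maps
    ]
    return image, masks, true_volumes


# ---------------------------------------------------------------------------
# TIFF plumbing


def read_image(path, pixel_size: float, chamber_height: float) -> ExclusionImage:
    """Read a single-channel 16-bit TIFF as an exclusion image."""
    import tifffile

    return ExclusionImage(
        pixels=tifffile.imread(path).astype(float),
        pixel_size=pixel_size,
        chamber_height=chamber_height,
    )


def write_image(path, image: ExclusionImage) -> None:
    import tifffile

    tifffile.imwrite(path, np.clip(image.pixels, 0, 65535).astype(np.uint16))


def read_mask(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path) > 0


def write_mask(path, mask: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))
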