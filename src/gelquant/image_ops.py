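"""Gel image I/O and pixel-level operations.

Images are single-channel grayscale grids (8- or 16-bit) with the row axis
running along the migration direction (row 0 = wells) and the column axis
across the lanes.  All coordinates are 0-based and ranges are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GelImage",
    "GrayHistogram",
    "OversaturationReport",
    "read_gel_image",
    "write_gel_image",
    "crop",
    "to_8bit",
    "histogram",
    "oversaturation",
    "auto_brightness_contrast",
]

_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass(frozen=True)
class GelImage:
    """A grayscale gel image.

    Parameters
    ----------
    pixels
        2-D array of non-negative integers; rows run along the migration
        axis (top = wells), columns across the gel.
    bit_depth
        8 or 16.
    pixel_size_um
        Optional physical scale in micrometres per pixel.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if self.bit_depth not in _DTYPES:
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be an integer array")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError(
                f"pixel values must lie in [0, {self.max_value}] for "
                f"{self.bit_depth}-bit images"
            )
        object.__setattr__(self, "pixels", px.astype(_DTYPES[self.bit_depth]))

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class GrayHistogram:
    """256-bin histogram spanning an image's own min..max pixel value."""

    bin_edges: np.ndarray  # 257 ascending values
    counts: np.ndarray  # 256 non-negative ints
    total_pixels: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=np.int64)
        if edges.shape != (257,) or counts.shape != (256,):
            raise ValueError("histogram needs 257 edges and 256 counts")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
        if counts.sum() != self.total_pixels:
            raise ValueError("counts must sum to total_pixels")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class OversaturationReport:
    """Percentage of pixels in the extreme histogram bins.

    "Black" is the lowest-value bin and "white" the highest, matching a
    light-background gel scan where stained bands are dark.
    """

    over_black_pct: float
    over_white_pct: float


def read_gel_image(path: str | Path) -> GelImage:
    """Read a single-channel 8- or 16-bit grayscale TIFF.

    Multi-channel (RGB) and multi-page files are rejected: quantitative
    densitometry is defined on a single grayscale plane.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise ValueError(
                f"{path}: multi-page TIFF ({len(tif.pages)} pages) is not supported"
            )
        arr = tif.pages[0].asarray()
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel grayscale image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path}: unsupported pixel type {arr.dtype}; need uint8/uint16")
    return GelImage(pixels=arr, bit_depth=depth)


def write_gel_image(image: GelImage, path: str | Path) -> None:
    """Write the image as a single-page grayscale TIFF (bit-exact round-trip)."""
    tifffile.imwrite(Path(path), image.pixels, photometric="minisblack")


def crop(image: GelImage, top: int, left: int, height: int, width: int) -> GelImage:
    """Extract the half-open rectangle [top, top+height) x [left, left+width)."""
    n, m = image.shape
    if height < 1 or width < 1:
        raise ValueError("crop height and width must be positive")
    if top < 0 or left < 0 or top + height > n or left + width > m:
        raise ValueError(
            f"crop rectangle [{top}:{top + height}, {left}:{left + width}] "
            f"exceeds image shape {image.shape}"
        )
    return replace(image, pixels=image.pixels[top : top + height, left : left + width].copy())


def to_8bit(image: GelImage) -> GelImage:
    """Convert to 8-bit by fixed full-range scaling, v8 = round(v16/257).

    The scaling is independent of image content (0 -> 0, 65535 -> 255):
    the optical-density copy must not depend on per-image display ranges,
    since the quantification protocol forbids brightness/contrast
    adjustment.  8-bit input is returned unchanged.
    """
    if image.bit_depth == 8:
        return image
    v8 = np.floor(image.pixels.astype(np.float64) / 257.0 + 0.5).astype(np.uint8)
    return GelImage(pixels=v8, bit_depth=8, pixel_size_um=image.pixel_size_um)


def histogram(image: GelImage) -> GrayHistogram:
    """256 equal-width bins spanning the image's own min..max pixel value.

    A constant image yields a degenerate range; by convention all pixels
    land in the first bin and the edges span [v, v+1].
    """
    px = image.pixels
    lo, hi = int(px.min()), int(px.max())
    if lo == hi:
        edges = np.linspace(lo, lo + 1, 257)
        counts = np.zeros(256, dtype=np.int64)
        counts[0] = px.size
    else:
        counts, edges = np.histogram(px, bins=256, range=(lo, hi))
    return GrayHistogram(bin_edges=edges, counts=counts, total_pixels=px.size)


def oversaturation(hist: GrayHistogram) -> OversaturationReport:
    """Fraction of pixels in the lowest (black) and highest (white) bins."""
    total = hist.total_pixels
    return OversaturationReport(
        over_black_pct=100.0 * hist.counts[0] / total,
        over_white_pct=100.0 * hist.counts[-1] / total,
    )


def auto_brightness_contrast(
    image: GelImage, saturated_fraction: float = 0.0035
) -> GelImage:
    """Automatic contrast stretch saturating a fixed fraction of pixels.

    Cut values are chosen from the 256-bin histogram so that at most
    ``saturated_fraction / 2`` of the pixels fall below the low cut and
    above the high cut; the interval [low, high] is then linearly
    stretched to the full bit-depth range with clipping.  This is the
    conventional "auto" display adjustment; it destroys quantitative
    linearity and is provided only so its effect on oversaturation can be
    measured.
    """
    if not 0.0 <= saturated_fraction < 1.0:
        raise ValueError("saturated_fraction must lie in [0, 1)")
    px = image.pixels
    hist = histogram(image)
    threshold = saturated_fraction / 2.0 * hist.total_pixels
    cum = np.cumsum(hist.counts)
    # lowest bin index where the cumulative count exceeds the saturation budget
    lo_bin = int(np.searchsorted(cum, threshold, side="right"))
    cum_hi = np.cumsum(hist.counts[::-1])
    hi_bin = 255 - int(np.searchsorted(cum_hi, threshold, side="right"))
    low = hist.bin_edges[lo_bin]
    high = hist.bin_edges[hi_bin + 1]
    if high <= low:  # fully saturated or constant image: nothing to stretch
        return image
    m = image.max_value
    stretched = (px.astype(np.float64) - low) / (high - low) * m
    out = np.clip(np.floor(stretched + 0.5), 0, m).astype(_DTYPES[image.bit_depth])
    return replace(image, pixels=out)
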