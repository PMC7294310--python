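"""Lane profiles and baseline-anchored peak integration.

A lane profile is the 1-D signal obtained by averaging pixel values
laterally across a fixed-width lane selection, indexed by migration
distance (row).  Profiles come in two flavours: raw grayscale, and
uncalibrated optical density OD = log10(255 / pixel value) computed on an
8-bit copy of the image — a stain-density proxy that is the protocol's
preferred quantitation signal.

Peak areas are taken above a straight baseline drawn between the peak's
two boundary points, mirroring the manual baseline of classic gel
densitometry; the area (units pixel*AU) is the quantity calibrated
against protein load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .image_ops import GelImage, to_8bit

__all__ = [
    "LaneSpec",
    "LaneProfile",
    "Peak",
    "uncalibrated_od",
    "extract_lane_profile",
    "integrate_peak",
    "auto_peak_bounds",
    "od_of_mean",
    "check_lane_width",
]

MAX_OD = float(np.log10(255.0))

ProfileMode = Literal["grayscale", "uncalibrated_od"]


@dataclass(frozen=True)
class LaneSpec:
    """Placement of a lane selection on the image.

    The selection is ``width_px`` columns wide, centred on ``center_col``,
    spanning rows ``row_range`` (half-open).  The conventional width is
    16 px, which should be at least ~30% of the physical well width.
    """

    center_col: int
    width_px: int = 16
    row_range: tuple[int, int] | None = None
    label: str = ""

    def column_range(self) -> tuple[int, int]:
        left = self.center_col - self.width_px // 2
        return left, left + self.width_px


@dataclass(frozen=True)
class LaneProfile:
    positions: np.ndarray  # migration-axis pixel indices
    values: np.ndarray  # per-position mean signal
    mode: ProfileMode
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        val = np.asarray(self.values, dtype=np.float64)
        if pos.shape != val.shape or pos.ndim != 1:
            raise ValueError("positions and values must be 1-D and equal length")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def value_at(self, pos: int) -> float:
        idx = pos - int(self.positions[0])
        if idx < 0 or idx >= len(self.values):
            raise IndexError(f"position {pos} outside profile range")
        return float(self.values[idx])


@dataclass(frozen=True)
class Peak:
    """A band's integrated signal above a straight baseline.

    ``area`` is the sum of max(0, profile - baseline) over the inclusive
    interval [left_pos, right_pos], in pixel*AU; ``max_intensity`` and
    ``centroid_pos`` are computed on the same baseline-subtracted signal.
    """

    left_pos: int
    right_pos: int
    baseline_left_value: float
    baseline_right_value: float
    area: float
    max_intensity: float
    centroid_pos: float


def uncalibrated_od(pixel_value_8bit):
    """Uncalibrated optical density of an 8-bit pixel: log10(255 / v).

    Pixel value 0 (pure black) would be infinite and is clamped to 1, so
    the OD range is [0, log10(255)].  Accepts scalars or arrays.
    """
    v = np.asarray(pixel_value_8bit, dtype=np.float64)
    if np.any(v < 0) or np.any(v > 255):
        raise ValueError("8-bit pixel values must lie in [0, 255]")
    od = np.log10(255.0 / np.maximum(v, 1.0))
    return float(od) if np.isscalar(pixel_value_8bit) else od


def extract_lane_profile(
    image: GelImage, lane: LaneSpec, mode: ProfileMode = "uncalibrated_od"
) -> LaneProfile:
    """Average the lane selection laterally into a 1-D migration profile.

    In OD mode the image is first reduced to its 8-bit copy and the OD
    transform is applied per pixel *before* lateral averaging (the
    transform is nonlinear, so the order matters; the per-pixel
    convention is the default and the alternative mean-then-transform is
    available via ``od_of_mean``).
    """
    if lane.width_px < 1:
        raise ValueError("lane width must be >= 1 pixel")
    n, m = image.shape
    left, right = lane.column_range()
    lo, hi = lane.row_range if lane.row_range is not None else (0, n)
    if left < 0 or right > m or lo < 0 or hi > n or lo >= hi:
        raise ValueError(
            f"lane selection [{lo}:{hi}, {left}:{right}] outside image {image.shape}"
        )
    if mode == "uncalibrated_od":
        block = to_8bit(image).pixels[lo:hi, left:right]
        values = uncalibrated_od(block).mean(axis=1)
    elif mode == "grayscale":
        values = image.pixels[lo:hi, left:right].astype(np.float64).mean(axis=1)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    return LaneProfile(
        positions=np.arange(lo, hi), values=values, mode=mode, label=lane.label
    )


def od_of_mean(image: GelImage, lane: LaneSpec) -> LaneProfile:
    """OD profile under the alternative convention: average the 8-bit
    grayscale laterally first, then apply the OD transform to the mean."""
    gray = extract_lane_profile(to_8bit(image), lane, mode="grayscale")
    return LaneProfile(
        positions=gray.positions,
        values=uncalibrated_od(gray.values.round().astype(np.int64)),
        mode="uncalibrated_od",
        label=lane.label,
    )


def integrate_peak(profile: LaneProfile, left_pos: int, right_pos: int) -> Peak:
    """Integrate a peak above the straight line joining its two endpoints.

    The baseline is the linear interpolation between the profile values
    at ``left_pos`` and ``right_pos``; negative excursions below it are
    clipped to zero (manual baselines touch the profile at both ends, so
    dips below the line are noise).  Area has units pixel*AU.
    """
    p0, p1 = int(profile.positions[0]), int(profile.positions[-1])
    if not (p0 <= left_pos < right_pos <= p1):
        raise ValueError(
            f"peak bounds [{left_pos}, {right_pos}] invalid for profile "
            f"spanning [{p0}, {p1}]"
        )
    i0, i1 = left_pos - p0, right_pos - p0
    seg = profile.values[i0 : i1 + 1]
    baseline = np.linspace(seg[0], seg[-1], len(seg))
    signal = np.maximum(seg - baseline, 0.0)
    area = float(signal.sum())
    if area > 0:
        centroid = float((signal * np.arange(left_pos, right_pos + 1)).sum() / area)
    else:
        centroid = (left_pos + right_pos) / 2.0
    return Peak(
        left_pos=left_pos,
        right_pos=right_pos,
        baseline_left_value=float(seg[0]),
        baseline_right_value=float(seg[-1]),
        area=area,
        max_intensity=float(signal.max()),
        centroid_pos=centroid,
    )


def auto_peak_bounds(
    profile: LaneProfile, prominence_fraction: float = 0.05
) -> list[tuple[int, int]]:
    """Detect peak intervals automatically (a convenience; the protocol's
    quantitative results use explicitly supplied bounds).

    Candidate peaks are local maxima with prominence at least
    ``prominence_fraction`` of the profile's dynamic range; each peak's
    bounds are the nearest flanking local minima (or the profile ends).
    Returned left-to-right and non-overlapping.
    """
    if not 0.0 < prominence_fraction < 1.0:
        raise ValueError("prominence_fraction must lie in (0, 1)")
    v = profile.values
    vrange = float(v.max() - v.min())
    if vrange == 0.0:
        return []
    idx, _ = find_peaks(v, prominence=prominence_fraction * vrange)
    if len(idx) == 0:
        return []
    p0 = int(profile.positions[0])
    bounds: list[tuple[int, int]] = []
    prev_right = 0
    for k, pk in enumerate(idx):
        left = pk
        while left > prev_right and v[left - 1] <= v[left]:
            left -= 1
        nxt = idx[k + 1] if k + 1 < len(idx) else len(v) - 1
        right = pk
        while right < nxt and v[right + 1] <= v[right]:
            right += 1
        if right > left:
            bounds.append((p0 + left, p0 + right))
            prev_right = right
    return bounds


def check_lane_width(width_px: int, well_width_px: int) -> None:
    """Warn when the lane selection is narrower than 30% of the well."""
    if width_px < 0.3 * well_width_px:
        warnings.warn(
            f"lane width {width_px} px is below 30% of the declared well "
            f"width {well_width_px} px; profiles may under-sample the band",
            stacklevel=2,
        )
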