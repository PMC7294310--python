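"""Seeded synthetic gel images with ground truth.

The generator emulates the statistical structure the densitometry
protocol relies on, so every processing stage can be tested without any
scanned gel:

* bands are dark on a light ground (stained-gel convention) and compose
  **additively in optical density**: each band contributes a Gaussian OD
  profile along the migration axis with a smooth lateral plateau, and
  pixel values are the background attenuated multiplicatively,
  ``px = bg * 10**(-sum OD)``.  This makes the baseline-subtracted
  OD-profile area of a band exactly proportional to its protein load
  (area = load_ng * response_au_per_ng), which is the linearity the
  quantification model assumes;
* the background may carry a linear per-row drift (illumination/stain
  gradient) that rolling-ball subtraction is expected to remove;
* noise is optional: additive Gaussian pixel noise (``noise_sd``) and a
  per-band multiplicative response scatter (``amplitude_cv``) standing
  in for staining variability.

A slight (+/-2%) antisymmetric lateral tilt is applied across each
band's plateau; it averages to exactly 1 over a centred 16-px lane
selection, so areas are unchanged, while it dithers the integer
quantization of pixel values across the averaged columns.

Identical seeds give bit-identical images.  The ground-truth table lists
each band's true load, analytic OD area, position, suggested integration
bounds, and whether the load is a real manufacturer figure or a
placeholder (marker bands whose load the manufacturer does not state are
flagged ``quantitative = False`` and must not anchor calibrations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_ops import GelImage
from .quantification import MarkerBand, load_marker_table

__all__ = [
    "SyntheticBandSpec",
    "SyntheticLane",
    "SyntheticGelSpec",
    "generate_gel",
    "marker_lane_fixture",
    "marker_gel_spec",
    "DEFAULT_RESPONSE_AU_PER_NG",
]

#: default band response: OD*pixel of profile area per ng of protein.
#: Chosen so the 750 ng reference band peaks near OD 0.6 at sigma 3.5 px
#: (a strongly stained but unsaturated band).
DEFAULT_RESPONSE_AU_PER_NG = 0.007

_LATERAL_ROLLOFF = 4  # cosine edge width, px
_LATERAL_TILT = 0.02  # antisymmetric dither amplitude across the plateau


@dataclass(frozen=True)
class SyntheticBandSpec:
    """Ground truth for one band."""

    mw_kda: float
    load_ng: float
    center_row: float
    sigma_rows: float = 3.5
    lateral_extent_cols: int = 24
    quantitative: bool = True  # False: placeholder load, not a mass standard

    def __post_init__(self) -> None:
        if self.load_ng < 0 or self.sigma_rows <= 0:
            raise ValueError("load_ng must be >= 0 and sigma_rows > 0")


@dataclass(frozen=True)
class SyntheticLane:
    center_col: int
    bands: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))


@dataclass(frozen=True)
class SyntheticGelSpec:
    shape: tuple[int, int]
    lanes: tuple
    bit_depth: int = 16
    background_level: float | None = None  # default: full white (2^depth - 1)
    background_gradient: float = 0.0  # pixel value change per row
    noise_sd: float = 0.0  # additive Gaussian pixel noise
    amplitude_cv: float = 0.0  # per-band multiplicative response scatter
    response_au_per_ng: float = DEFAULT_RESPONSE_AU_PER_NG
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(self.lanes))
        maxval = (1 << self.bit_depth) - 1
        level = maxval if self.background_level is None else self.background_level
        if not 0 < level <= maxval:
            raise ValueError("background_level outside the bit-depth range")
        object.__setattr__(self, "background_level", float(level))


def _lateral_profile(cols: np.ndarray, center_col: int, extent: int) -> np.ndarray:
    """Smooth plateau with cosine edges and an antisymmetric ~2% tilt.

    The tilt is centred on (center_col - 0.5) so it averages to exactly 1
    over a 16-px lane selection centred on ``center_col``.
    """
    dc = cols.astype(np.float64) - (center_col - 0.5)
    half = extent / 2.0
    core = half - _LATERAL_ROLLOFF
    out = np.zeros_like(dc)
    inner = np.abs(dc) <= core
    out[inner] = 1.0 + _LATERAL_TILT * dc[inner] / core
    edge = (np.abs(dc) > core) & (np.abs(dc) <= half)
    sign = np.sign(dc[edge])
    edge_val = 1.0 + _LATERAL_TILT * sign
    frac = (np.abs(dc[edge]) - core) / _LATERAL_ROLLOFF
    out[edge] = edge_val * 0.5 * (1.0 + np.cos(np.pi * frac))
    return out


def generate_gel(spec: SyntheticGelSpec) -> tuple[GelImage, pd.DataFrame]:
    """Render the gel and return it with its ground-truth band table.

    The table has one row per band with the true load, the analytic
    OD-profile area (load * response * amplitude factor), the band
    position and suggested integration bounds (centre +/- 4 sigma), and
    an ``overlaps`` flag set when neighbouring integration windows
    intersect (a warning is emitted as well).
    """
    n, m = spec.shape
    maxval = (1 << spec.bit_depth) - 1
    rng = np.random.default_rng(spec.seed)
    rows = np.arange(n, dtype=np.float64)
    cols = np.arange(m, dtype=np.float64)

    od = np.zeros((n, m))
    records = []
    for lane_idx, lane in enumerate(spec.lanes):
        for band in lane.bands:
            amp = 1.0
            if spec.amplitude_cv > 0:
                amp = max(0.0, 1.0 + spec.amplitude_cv * rng.standard_normal())
            od_area = band.load_ng * spec.response_au_per_ng * amp
            gauss = (
                od_area
                / (band.sigma_rows * np.sqrt(2.0 * np.pi))
                * np.exp(-((rows - band.center_row) ** 2) / (2.0 * band.sigma_rows**2))
            )
            lateral = _lateral_profile(cols, lane.center_col, band.lateral_extent_cols)
            od += np.outer(gauss, lateral)
            records.append(
                {
                    "lane_index": lane_idx,
                    "lane_label": lane.label,
                    "center_col": lane.center_col,
                    "mw_kda": band.mw_kda,
                    "load_ng": band.load_ng,
                    "quantitative": band.quantitative,
                    "center_row": band.center_row,
                    "sigma_rows": band.sigma_rows,
                    "od_area_analytic": od_area,
                    "left_bound": int(round(band.center_row - 4 * band.sigma_rows)),
                    "right_bound": int(round(band.center_row + 4 * band.sigma_rows)),
                }
            )
    columns = [
        "lane_index", "lane_label", "center_col", "mw_kda", "load_ng",
        "quantitative", "center_row", "sigma_rows", "od_area_analytic",
        "left_bound", "right_bound",
    ]
    truth = pd.DataFrame.from_records(records, columns=columns)

    # flag bands whose integration windows collide within a lane
    truth["overlaps"] = False
    for lane_idx, grp in truth.groupby("lane_index"):
        g = grp.sort_values("center_row")
        clash = g["left_bound"].values[1:] <= g["right_bound"].values[:-1]
        if clash.any():
            idx = g.index.values
            truth.loc[idx[:-1][clash], "overlaps"] = True
            truth.loc[idx[1:][clash], "overlaps"] = True
            warnings.warn(
                f"lane {lane_idx}: overlapping band integration windows",
                stacklevel=2,
            )

    bg = spec.background_level + spec.background_gradient * rows[:, None]
    if bg.max() > maxval or bg.min() <= 0:
        warnings.warn("background drifts outside the valid pixel range; clipping",
                      stacklevel=2)
    px = np.clip(bg, 1.0, maxval) * 10.0 ** (-od)
    if spec.noise_sd > 0:
        px = px + rng.normal(0.0, spec.noise_sd, size=px.shape)
    px_int = np.clip(np.floor(px + 0.5), 0, maxval)
    if (px_int == 0).any():
        warnings.warn(
            "bands saturate to pure black; reduce response_au_per_ng or loads",
            stacklevel=2,
        )
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = GelImage(pixels=px_int.astype(dtype), bit_depth=spec.bit_depth)
    return image, truth


# ---------------------------------------------------------------------------
# Marker-lane fixture


#: placeholder loads (ng per 10 ul) for marker bands without a stated load:
#: ordinary bands get the 150 ng of the characterized ordinary bands, the 3x
#: reference bands 450 ng.  These are NOT manufacturer figures; bands carrying
#: them are flagged quantitative=False.
_PLACEHOLDER_ORDINARY_NG = 150.0
_PLACEHOLDER_REFERENCE_NG = 450.0


def marker_lane_fixture(
    volume_ul: float,
    response_au_per_ng: float = DEFAULT_RESPONSE_AU_PER_NG,
    row_span: tuple[float, float] = (40.0, 480.0),
    sigma_rows: float = 3.5,
    bands: list[MarkerBand] | None = None,
) -> list[SyntheticBandSpec]:
    """Ten-band molecular-weight-marker lane for a given loaded volume.

    Band centres are placed linearly in log10(MW) across ``row_span``
    (an idealized migration law).  Bands with a manufacturer-stated load
    carry ``load_ng_per_10ul * volume/10``; the others carry documented
    placeholder loads and are flagged non-quantitative.
    """
    if volume_ul <= 0:
        raise ValueError("volume_ul must be positive")
    table = bands if bands is not None else load_marker_table()
    logs = np.log10([b.mw_kda for b in table])
    lo, hi = logs.max(), logs.min()  # largest MW at the top of the span
    r0, r1 = row_span
    specs = []
    for band, lg in zip(table, logs):
        center = r0 + (lo - lg) / (lo - hi) * (r1 - r0)
        load = band.load_ng(volume_ul)
        if load is None:
            base = _PLACEHOLDER_REFERENCE_NG if band.is_reference else _PLACEHOLDER_ORDINARY_NG
            specs.append(
                SyntheticBandSpec(
                    mw_kda=band.mw_kda,
                    load_ng=base * volume_ul / 10.0,
                    center_row=center,
                    sigma_rows=sigma_rows,
                    quantitative=False,
                )
            )
        else:
            specs.append(
                SyntheticBandSpec(
                    mw_kda=band.mw_kda,
                    load_ng=load,
                    center_row=center,
                    sigma_rows=sigma_rows,
                    quantitative=True,
                )
            )
    return specs


def marker_gel_spec(
    volume_ul: float = 10.0,
    seed: int = 0,
    shape: tuple[int, int] = (520, 64),
    center_col: int = 32,
    noise_sd: float = 0.0,
    background_gradient: float = 0.0,
    response_au_per_ng: float = DEFAULT_RESPONSE_AU_PER_NG,
) -> SyntheticGelSpec:
    """A complete single-lane marker gel specification."""
    lane = SyntheticLane(
        center_col=center_col,
        bands=marker_lane_fixture(volume_ul, response_au_per_ng),
        label=f"marker {volume_ul:g} ul",
    )
    return SyntheticGelSpec(
        shape=shape,
        lanes=(lane,),
        background_gradient=background_gradient,
        noise_sd=noise_sd,
        response_au_per_ng=response_au_per_ng,
        seed=seed,
    )
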