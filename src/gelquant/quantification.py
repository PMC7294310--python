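"""Protein load arithmetic, calibration regression, and band quantification.

The calibration model is a zero-intercept (through-origin) least-squares
line A = slope * P between peak area A (pixel*AU) and protein load P (ng).
Through-origin inference uses the standard conventions: slope standard
error with n-1 degrees of freedom and the uncentered coefficient of
determination R^2 = 1 - SS_res / sum(A^2).

Two calibration routes are supported:

* multi-point: a dilution series of a protein standard (or the
  characterized marker bands) fitted through the origin, with slope SE,
  R^2 and a two-sided p-value for slope = 0;
* single-point: the 50 kDa marker reference band, whose manufacturer
  load (750 ng per 10 ul lane) anchors the slope directly; SE, R^2 and p
  are undefined for a one-point model and are reported as None.

Molecular weights of unknown bands are estimated by piecewise-linear
interpolation of log10(MW) against migration position between the
flanking marker bands.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .densitometry import Peak

__all__ = [
    "ProteinStandard",
    "MarkerBand",
    "MarkerLane",
    "CalibrationModel",
    "QuantifiedBand",
    "load_marker_table",
    "beer_lambert_concentration",
    "mixture_concentrations",
    "protein_load",
    "fit_zero_intercept",
    "calibrate_from_marker",
    "quantify_band",
    "estimate_mw",
    "culture_concentration",
    "intensity_ratio_report",
]


@dataclass(frozen=True)
class ProteinStandard:
    """A protein standard characterized by UV absorbance at 280 nm."""

    name: str
    mw_kda: float
    epsilon_1pct: float  # percent extinction coefficient (1% w/v, 1 cm)
    concentration_mg_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon_1pct <= 0:
            raise ValueError("epsilon_1pct must be positive")
        if self.concentration_mg_ml < 0:
            raise ValueError("concentration cannot be negative")


@dataclass(frozen=True)
class MarkerBand:
    """One band of the molecular-weight marker ladder.

    ``load_ng_per_10ul`` is the manufacturer-stated protein mass for a
    10 ul lane; it scales linearly with loaded volume.  None means the
    manufacturer does not state a load and the band must not be used as
    a mass standard.
    """

    mw_kda: float
    load_ng_per_10ul: float | None = None
    is_reference: bool = False

    def load_ng(self, volume_ul: float) -> float | None:
        if self.load_ng_per_10ul is None:
            return None
        return self.load_ng_per_10ul * volume_ul / 10.0


@dataclass(frozen=True)
class MarkerLane:
    """Marker band definitions paired with their measured peaks.

    Bands are kept in migration order (decreasing MW, increasing
    centroid position); this ordering is validated because MW
    interpolation relies on it.
    """

    volume_ul: float
    bands: tuple  # of (MarkerBand, Peak)

    def __post_init__(self) -> None:
        bands = tuple(self.bands)
        mws = [b.mw_kda for b, _ in bands]
        cents = [p.centroid_pos for _, p in bands]
        if any(a >= b for a, b in zip(mws[1:], mws[:-1])):
            raise ValueError("marker bands must be in decreasing-MW order")
        if any(a <= b for a, b in zip(cents[1:], cents[:-1])):
            raise ValueError(
                "marker centroids must strictly increase as MW decreases"
            )
        object.__setattr__(self, "bands", bands)

    def band(self, mw_kda: float) -> tuple[MarkerBand, Peak]:
        for b, p in self.bands:
            if b.mw_kda == mw_kda:
                return b, p
        raise KeyError(f"no marker band at {mw_kda} kDa")


@dataclass(frozen=True)
class CalibrationModel:
    """A = slope * P mapping between peak area and protein load."""

    slope: float  # pixel*AU per ng
    slope_se: float | None
    r2: float | None
    p_value: float | None
    n_points: int
    source: Literal["multi-point", "single-point-marker"]

    def __post_init__(self) -> None:
        # a fit over degenerate data may have slope <= 0; such a model is
        # constructible (e.g. to inspect its statistics) but operations
        # that divide by the slope refuse to use it
        if not np.isfinite(self.slope):
            raise ValueError("calibration slope must be finite")


@dataclass(frozen=True)
class QuantifiedBand:
    load_ng: float
    mw_kda_est: float | None
    lane_label: str
    peak: Peak


def load_marker_table(path: str | Path | None = None) -> list[MarkerBand]:
    """Load a marker definition table (JSON); defaults to the packaged
    ten-band unstained ladder (250..10 kDa, 750 ng at 50 kDa per 10 ul)."""
    if path is None:
        text = (
            resources.files("gelquant.data")
            .joinpath("precision_plus_unstained.json")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return [
        MarkerBand(
            mw_kda=float(b["mw_kda"]),
            load_ng_per_10ul=(
                None if b.get("load_ng_per_10ul") is None else float(b["load_ng_per_10ul"])
            ),
            is_reference=bool(b.get("is_reference", False)),
        )
        for b in raw["bands"]
    ]


def beer_lambert_concentration(
    a280: float, epsilon_1pct: float, path_cm: float
) -> float:
    """Concentration (mg/ml) from A280 via the Beer-Lambert law.

    C[% w/v] = A280 / (epsilon_1pct * l); a 1% w/v solution is 10 mg/ml,
    hence the factor 10.
    """
    if epsilon_1pct <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    if a280 < 0:
        raise ValueError("absorbance cannot be negative")
    return a280 / (epsilon_1pct * path_cm) * 10.0


def mixture_concentrations(
    stocks: Sequence[tuple[str, float, float]],
) -> list[tuple[str, float]]:
    """Concentrations of each component after mixing stock volumes.

    ``stocks`` is a sequence of (name, concentration mg/ml, volume ul);
    each output concentration is C_i * V_i / V_total.
    """
    if not stocks:
        raise ValueError("at least one stock is required")
    total = sum(v for _, _, v in stocks)
    if total <= 0:
        raise ValueError("total volume must be positive")
    return [(name, c * v / total) for name, c, v in stocks]


def protein_load(
    concentration_mg_ml: float, volume_ul: float, dilution_factor: float = 0.5
) -> float:
    """Protein mass (ng) loaded in a well: P = C * V * dilution * 1000.

    The default dilution factor 1/2 reflects the 1:1 sample dilution in
    Laemmli buffer; the factor 1000 bridges mg/ml * ul to ng.
    """
    if concentration_mg_ml < 0 or volume_ul < 0 or dilution_factor < 0:
        raise ValueError("inputs must be non-negative")
    return concentration_mg_ml * volume_ul * dilution_factor * 1000.0


def fit_zero_intercept(points: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Least-squares fit of A = slope * P through the origin.

    slope = sum(A*P) / sum(P^2); slope SE uses n-1 degrees of freedom;
    R^2 is the uncentered through-origin convention
    1 - SS_res / sum(A^2); the p-value is the two-sided t-test of
    slope / SE with n-1 df.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (load, area) points")
    P, A = pts[:, 0], pts[:, 1]
    sp2 = float((P * P).sum())
    if sp2 == 0.0:
        raise ValueError("degenerate design: all loads are zero")
    n = len(P)
    slope = float((A * P).sum() / sp2)
    resid = A - slope * P
    ss_res = float((resid * resid).sum())
    se = float(np.sqrt(ss_res / ((n - 1) * sp2)))
    ss_tot = float((A * A).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if se > 0:
        t = slope / se
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    else:  # exact fit
        p = float(np.finfo(float).tiny)
    return CalibrationModel(
        slope=slope, slope_se=se, r2=r2, p_value=p, n_points=n, source="multi-point"
    )


def calibrate_from_marker(
    marker: MarkerLane, reference_mw_kda: float = 50.0
) -> CalibrationModel:
    """Single-point calibration anchored on a marker reference band.

    slope = area(reference band) / load, where the load is the
    manufacturer's 10 ul figure scaled by the lane's actual volume.
    Uncertainty statistics are undefined for a one-point model.
    """
    try:
        band, peak = marker.band(reference_mw_kda)
    except KeyError as exc:
        raise ValueError(
            f"marker lane has no band at {reference_mw_kda} kDa"
        ) from exc
    load = band.load_ng(marker.volume_ul)
    if load is None:
        raise ValueError(
            f"marker band {reference_mw_kda} kDa has no manufacturer-stated load "
            "and cannot anchor a calibration"
        )
    if peak.area <= 0:
        raise ValueError(f"reference band at {reference_mw_kda} kDa has zero area")
    return CalibrationModel(
        slope=peak.area / load,
        slope_se=None,
        r2=None,
        p_value=None,
        n_points=1,
        source="single-point-marker",
    )


def fit_marker_multipoint(marker: MarkerLane) -> CalibrationModel:
    """Through-origin fit over all marker bands with stated loads
    (the alternative to the single-point 50 kDa anchor)."""
    pts = [
        (band.load_ng(marker.volume_ul), peak.area)
        for band, peak in marker.bands
        if band.load_ng_per_10ul is not None
    ]
    if len(pts) < 2:
        raise ValueError("marker lane has fewer than two characterized bands")
    return fit_zero_intercept(pts)


def quantify_band(peak: Peak, model: CalibrationModel) -> float:
    """Protein load (ng) of a band: area / slope."""
    if model.slope <= 0:
        raise ValueError("calibration slope must be positive")
    return peak.area / model.slope


def estimate_mw(centroid_pos: float, marker: MarkerLane) -> float:
    """Molecular weight (kDa) at a migration position, by piecewise-linear
    interpolation of log10(MW) against the marker band centroids.

    Positions outside the marker span are extrapolated linearly from the
    nearest segment, with a warning.
    """
    if len(marker.bands) < 2:
        raise ValueError("MW estimation needs at least two marker bands")
    cents = np.array([p.centroid_pos for _, p in marker.bands])
    logmw = np.log10([b.mw_kda for b, _ in marker.bands])
    if centroid_pos < cents[0] or centroid_pos > cents[-1]:
        warnings.warn(
            f"position {centroid_pos:.1f} outside the marker span "
            f"[{cents[0]:.1f}, {cents[-1]:.1f}]; extrapolating",
            stacklevel=2,
        )
        if centroid_pos < cents[0]:
            seg = slice(0, 2)
        else:
            seg = slice(-2, None)
        x, y = cents[seg], logmw[seg]
        val = y[0] + (y[1] - y[0]) * (centroid_pos - x[0]) / (x[1] - x[0])
    else:
        val = float(np.interp(centroid_pos, cents, logmw))
    return float(10.0 ** val)


def estimate_mw_global_fit(centroid_pos: float, marker: MarkerLane) -> float:
    """MW estimate from a single global log-linear regression of log10(MW)
    on centroid position across all marker bands (alternative to the
    piecewise interpolant)."""
    cents = np.array([p.centroid_pos for _, p in marker.bands])
    logmw = np.log10([b.mw_kda for b, _ in marker.bands])
    if len(cents) < 2:
        raise ValueError("MW estimation needs at least two marker bands")
    slope, intercept = np.polyfit(cents, logmw, 1)
    return float(10.0 ** (slope * centroid_pos + intercept))


def culture_concentration(
    eluates: Sequence[tuple[float, float]], culture_sample_volume_ml: float
) -> float:
    """Back-calculate a per-litre culture concentration from eluates.

    ``eluates`` is a sequence of (concentration mg/L of eluate,
    eluate volume ml).  By mass conservation the concentration in the
    original culture sample is sum(C_i * V_i) / V_sample (consistent
    volume units cancel, leaving mg/L).
    """
    if culture_sample_volume_ml <= 0:
        raise ValueError("culture sample volume must be positive")
    return sum(c * v for c, v in eluates) / culture_sample_volume_ml


def intensity_ratio_report(marker: MarkerLane) -> list[dict]:
    """Reference-to-neighbour band intensity ratios.

    The manufacturer states the reference bands (75, 50, 25 kDa) run at
    about three times the intensity of the other bands.  For each
    reference band this reports its ratio to the mean of its immediate
    non-reference neighbours, by both peak max intensity and peak area,
    so the ~3x expectation can be checked; no pass/fail threshold is
    imposed.
    """
    rows = []
    bands = marker.bands
    for i, (band, peak) in enumerate(bands):
        if not band.is_reference:
            continue
        neighbours = [
            p
            for j, (b, p) in enumerate(bands)
            if abs(j - i) == 1 and not b.is_reference
        ]
        if not neighbours:
            continue
        mean_max = float(np.mean([p.max_intensity for p in neighbours]))
        mean_area = float(np.mean([p.area for p in neighbours]))
        rows.append(
            {
                "reference_mw_kda": band.mw_kda,
                "ratio_by_max_intensity": peak.max_intensity / mean_max
                if mean_max > 0
                else float("nan"),
                "ratio_by_area": peak.area / mean_area
                if mean_area > 0
                else float("nan"),
            }
        )
    return rows
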