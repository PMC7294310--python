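"""End-to-end protocol runs: configuration, analysis, quantification.

The default configuration reproduces the selected quantification
protocol: crop (optional) -> no brightness/contrast adjustment ->
rolling-ball background subtraction at radius 250 -> uncalibrated-OD
lane profiles -> straight-baseline peak integration -> single-point
calibration on the 50 kDa marker reference band (750 ng per 10 ul lane).
Every processing choice is echoed into the run metadata so a run is
fully reproducible from its outputs.

Processing order is fixed as crop -> brightness/contrast (if enabled) ->
background subtraction -> profiles; oversaturation is reported on the
cropped working image after processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import image_ops
from .background import rolling_ball_background
from .densitometry import LaneSpec, extract_lane_profile, integrate_peak
from .image_ops import GelImage
from .quantification import (
    MarkerLane,
    QuantifiedBand,
    calibrate_from_marker,
    estimate_mw,
    fit_marker_multipoint,
    intensity_ratio_report,
    load_marker_table,
    quantify_band,
)

__all__ = ["LaneConfig", "RunConfig", "analyze", "quantify", "load_config"]


@dataclass
class LaneConfig:
    center_col: int
    peaks: list[tuple[int, int]]
    width_px: int = 16
    label: str = ""
    marker_volume_ul: float | None = None  # set => this lane is the marker
    band_mw_kda: list[float] | None = None  # marker only: MW of each peak, in order


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    Defaults are the selected protocol: rolling-ball radius 250, no
    brightness/contrast adjustment, uncalibrated-OD profiles, 50 kDa
    reference band.
    """

    image_path: str = ""
    lanes: list[LaneConfig] = field(default_factory=list)
    crop: tuple[int, int, int, int] | None = None  # top, left, height, width
    rolling_ball_radius: int = 250
    background_subtraction: bool = True
    light_background: bool = True
    brightness_contrast: bool = False
    saturated_fraction: float = 0.0035
    profile_mode: str = "uncalibrated_od"
    marker_table_path: str | None = None
    reference_mw_kda: float = 50.0
    marker_calibration: str = "single-point"  # or "multi-point"
    output_dir: str = "."
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON or YAML (JSON is a YAML subset)."""
    raw = yaml.safe_load(Path(path).read_text())
    lanes = [
        LaneConfig(
            center_col=int(l["center_col"]),
            peaks=[(int(a), int(b)) for a, b in l.get("peaks", [])],
            width_px=int(l.get("width_px", 16)),
            label=str(l.get("label", "")),
            marker_volume_ul=(
                float(l["marker_volume_ul"]) if l.get("marker_volume_ul") is not None else None
            ),
            band_mw_kda=(
                [float(x) for x in l["band_mw_kda"]] if l.get("band_mw_kda") else None
            ),
        )
        for l in raw.pop("lanes", [])
    ]
    crop_ = raw.pop("crop", None)
    cfg = RunConfig(lanes=lanes, crop=tuple(crop_) if crop_ else None, **raw)
    return cfg


def _metadata(config: RunConfig) -> dict:
    meta = asdict(config)
    meta["processing_order"] = [
        "crop",
        "brightness_contrast" if config.brightness_contrast else None,
        "background_subtraction" if config.background_subtraction else None,
        "profiles",
    ]
    meta["processing_order"] = [s for s in meta["processing_order"] if s]
    meta["od_convention"] = "per-pixel OD before lateral averaging"
    meta["oversaturation_computed_on"] = "cropped working image after processing"
    return meta


def analyze(config: RunConfig, image: GelImage | None = None) -> dict:
    """Run the processing chain and integrate all configured peaks.

    Returns a dict with the processed image, per-lane profiles, a peak
    table (DataFrame), the oversaturation report, and run metadata.
    """
    if image is None:
        image = image_ops.read_gel_image(config.image_path)
    if config.crop is not None:
        image = image_ops.crop(image, *config.crop)
    if config.brightness_contrast:
        image = image_ops.auto_brightness_contrast(image, config.saturated_fraction)
    if config.background_subtraction:
        result = rolling_ball_background(
            image, config.rolling_ball_radius, config.light_background
        )
        image = result.corrected
    sat = image_ops.oversaturation(image_ops.histogram(image))

    profiles = {}
    rows = []
    peaks = {}
    for lane in config.lanes:
        spec = LaneSpec(
            center_col=lane.center_col, width_px=lane.width_px, label=lane.label
        )
        profile = extract_lane_profile(image, spec, mode=config.profile_mode)
        profiles[lane.label] = profile
        lane_peaks = []
        for left, right in lane.peaks:
            pk = integrate_peak(profile, left, right)
            lane_peaks.append(pk)
            rows.append(
                {
                    "lane": lane.label,
                    "mode": config.profile_mode,
                    "left_pos": pk.left_pos,
                    "right_pos": pk.right_pos,
                    "area": pk.area,
                    "max_intensity": pk.max_intensity,
                    "centroid": pk.centroid_pos,
                }
            )
        peaks[lane.label] = lane_peaks

    return {
        "image": image,
        "profiles": profiles,
        "peaks": peaks,
        "peak_table": pd.DataFrame(rows),
        "oversaturation": sat,
        "metadata": _metadata(config),
    }


def _build_marker_lane(config: RunConfig, lane: LaneConfig, lane_peaks) -> MarkerLane:
    table = load_marker_table(config.marker_table_path)
    if lane.band_mw_kda is not None:
        by_mw = {b.mw_kda: b for b in table}
        try:
            bands = [by_mw[mw] for mw in lane.band_mw_kda]
        except KeyError as exc:
            raise ValueError(f"marker table has no band at {exc.args[0]} kDa") from exc
    else:
        if len(lane_peaks) != len(table):
            raise ValueError(
                f"marker lane {lane.label!r} has {len(lane_peaks)} peaks but the "
                f"table defines {len(table)} bands; supply band_mw_kda to map them"
            )
        bands = table
    return MarkerLane(
        volume_ul=lane.marker_volume_ul, bands=tuple(zip(bands, lane_peaks))
    )


def quantify(config: RunConfig, image: GelImage | None = None) -> dict:
    """Analyze, calibrate on the marker lane, and quantify all other bands.

    Exactly one lane must carry ``marker_volume_ul``.  Calibration is
    single-point on the reference band by default, or a through-origin
    fit over all characterized marker bands with
    ``marker_calibration = "multi-point"``.
    """
    analysis = analyze(config, image=image)
    marker_lanes = [l for l in config.lanes if l.marker_volume_ul is not None]
    if len(marker_lanes) != 1:
        raise ValueError(
            f"quantification needs exactly one marker lane, found {len(marker_lanes)}"
        )
    mlane_cfg = marker_lanes[0]
    marker = _build_marker_lane(config, mlane_cfg, analysis["peaks"][mlane_cfg.label])
    if config.marker_calibration == "multi-point":
        model = fit_marker_multipoint(marker)
    else:
        model = calibrate_from_marker(marker, config.reference_mw_kda)

    bands: list[QuantifiedBand] = []
    for lane in config.lanes:
        if lane is mlane_cfg:
            continue
        for pk in analysis["peaks"][lane.label]:
            bands.append(
                QuantifiedBand(
                    load_ng=quantify_band(pk, model),
                    mw_kda_est=estimate_mw(pk.centroid_pos, marker),
                    lane_label=lane.label,
                    peak=pk,
                )
            )
    analysis["calibration"] = model
    analysis["marker_lane"] = marker
    analysis["quantified_bands"] = bands
    analysis["quantified"] = pd.DataFrame(
        [
            {
                "lane": b.lane_label,
                "centroid": b.peak.centroid_pos,
                "area": b.peak.area,
                "slope_source": model.source,
                "load_ng": b.load_ng,
                "mw_kda_est": b.mw_kda_est,
            }
            for b in bands
        ]
    )
    analysis["intensity_ratios"] = intensity_ratio_report(marker)
    return analysis


def write_outputs(result: dict, output_dir: str | Path) -> list[Path]:
    """Write CSV/JSON artifacts for an analyze/quantify result."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    path = out / "peaks.csv"
    result["peak_table"].to_csv(path, index=False)
    written.append(path)

    sat = result["oversaturation"]
    path = out / "oversaturation.json"
    path.write_text(
        json.dumps(
            {
                "over_black_pct": sat.over_black_pct,
                "over_white_pct": sat.over_white_pct,
            },
            indent=2,
        )
    )
    written.append(path)

    if "quantified" in result:
        path = out / "quantified.csv"
        result["quantified"].to_csv(path, index=False)
        written.append(path)
        path = out / "intensity_ratios.json"
        path.write_text(json.dumps(result["intensity_ratios"], indent=2))
        written.append(path)

    path = out / "run_metadata.json"
    path.write_text(json.dumps(result["metadata"], indent=2, default=str))
    written.append(path)
    return written
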