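"""End-to-end run orchestration: phases CSV -> dances -> endpoints -> maps ->
search-area report, with a YAML config, a JSON report validated against a
shipped schema, and deterministic outputs.

A run reads a phase CSV, groups dances, resolves the calibration factor
(either given explicitly or estimated from a known feeder distance), geocodes
phase-level and dance-level endpoints, builds the density surface, and writes:

* ``dances.csv`` — per-dance summaries,
* ``endpoints_phases.geojson`` / ``endpoints_dances.geojson`` (+ CSV mirrors),
* ``density.asc`` — ESRI ASCII grid in the local tangent-plane CRS,
* ``report.json`` — search area, dance rate and sampling diagnostics,
* ``run.log`` — config echo and stage log.

Rerunning with the same config and inputs produces byte-identical CSV/JSON
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel

from .dances import (
    HiveSite,
    dance_rate,
    phases_to_dances,
    read_phases,
    write_dances,
)
from .errors import ConfigurationError, DanceMapError, ValidationError
from .geocode import (
    CalibrationModel,
    calibrate,
    dance_endpoints,
    nyquist_margin,
    phase_endpoints,
    ring_spacing,
    sector_width,
    waggle_accuracy,
    write_endpoints_csv,
    write_endpoints_geojson,
)
from .mapping import density_map, search_area, write_ascii_grid
from .solar import check_daylight, solar_position

__all__ = ["RunConfig", "SearchAreaReport", "run_pipeline", "diagnose", "report_schema"]

logger = logging.getLogger("dancemap")

_SCHEMA_PATH = Path(__file__).parent / "schemas" / "report.schema.json"


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.

    Exactly one calibration source must be given: an explicit ``v`` (m/s) or
    a known ``feeder_distance_m`` to calibrate against.
    """

    site: HiveSite
    v: Optional[float] = None
    feeder_distance_m: Optional[float] = None
    estimator: str = "median"
    bandwidth_m: float = 29.0
    cell_size_m: float = 5.0
    trim_fraction: float = 0.0
    coverage_fraction: float = 0.9
    waggle_freq_hz: float = 13.0
    max_signal_hz: float = 18.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.v is None) == (self.feeder_distance_m is None):
            raise ConfigurationError(
                "exactly one calibration source required: explicit v OR feeder_distance_m"
            )
        if self.v is not None and self.v <= 0:
            raise ConfigurationError("v must be positive")
        if self.feeder_distance_m is not None and self.feeder_distance_m <= 0:
            raise ConfigurationError("feeder_distance_m must be positive")
        if self.estimator not in ("median", "mean"):
            raise ConfigurationError(f"estimator must be median|mean, got {self.estimator!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        """Load a config from a YAML key-value file; keyword overrides win."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        site_keys = {
            "lat_deg", "lon_deg", "fps", "utc_offset_h", "frame_inner_width_mm",
        }
        site_raw = raw.pop("site", {})
        if not isinstance(site_raw, dict):
            raise ConfigurationError(f"{path}: 'site' must be a mapping")
        # allow flat site keys at top level as a convenience
        for k in list(raw):
            if k in site_keys:
                site_raw.setdefault(k, raw.pop(k))
        try:
            site = HiveSite(**site_raw)
        except (TypeError, ValidationError) as exc:
            raise ConfigurationError(f"{path}: invalid site: {exc}") from exc
        try:
            return cls(site=site, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: invalid config: {exc}") from exc


class SearchAreaReport(BaseModel):
    """Schema of ``report.json``; the JSON schema ships with the package
    (``dancemap/schemas/report.schema.json``)."""

    n_phases: int
    n_dances: int
    calibration_v: float
    calibration_v_rounded: int
    calibration_estimator: str
    calibration_n: Optional[int] = None
    dance_rate_per_min: Optional[float] = None
    dance_rate_rounded: Optional[int] = None
    session_span_min: Optional[float] = None
    peak_lat: float
    peak_lon: float
    circle_center_lat: float
    circle_center_lon: float
    circle_diameter_m: float
    sector_width_deg: float
    ring_spacing_m: float
    ring_spacing_rounded_m: int
    waggle_accuracy_m: float
    waggle_accuracy_rounded_m: int
    nyquist_margin: float
    nyquist_adequate: bool
    sampling_sufficient: bool
    n_night_phases: int


def report_schema() -> dict:
    """The published JSON schema for :class:`SearchAreaReport`."""
    with open(_SCHEMA_PATH, encoding="utf-8") as fh:
        return json.load(fh)


def _resolve_calibration(config: RunConfig, dances) -> CalibrationModel:
    if config.v is not None:
        return CalibrationModel(v=config.v, estimator="explicit", n=None)
    durations = [d.duration_estimate_s(config.estimator) for d in dances]
    return calibrate(durations, config.feeder_distance_m, estimator=config.estimator)


def diagnose(
    site: HiveSite,
    calibration: CalibrationModel | float,
    waggle_freq_hz: float,
    max_signal_hz: float,
) -> dict:
    """Sampling diagnostics for a site and calibration.

    ``sampling_sufficient`` holds iff the quantization ring spacing does not
    exceed the one-waggle ground accuracy — i.e. frame timing is not the
    limiting error source.
    """
    rs = ring_spacing(calibration, site.fps)
    wa = waggle_accuracy(calibration, waggle_freq_hz)
    nm = nyquist_margin(site.fps, max_signal_hz)
    return {
        "ring_spacing_m": rs.value,
        "ring_spacing_rounded_m": rs.rounded,
        "waggle_accuracy_m": wa.value,
        "waggle_accuracy_rounded_m": wa.rounded,
        "nyquist_margin": nm.ratio,
        "nyquist_adequate": nm.adequate,
        "sampling_sufficient": rs.value <= wa.value,
    }


def run_pipeline(config: RunConfig, phase_csv, out_dir) -> dict:
    """Run the full pipeline; returns a dict of artifact paths plus the
    parsed report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    try:
        logger.info("config: %s", json.dumps(_config_echo(config), sort_keys=True))

        stage = "read_phases"
        phases = read_phases(phase_csv)
        if not phases:
            raise ValidationError(f"{phase_csv}: no phases to process")
        logger.info("read %d phases from %s", len(phases), phase_csv)

        stage = "phases_to_dances"
        dances = phases_to_dances(phases, config.site.fps)
        logger.info("grouped %d dances", len(dances))

        stage = "calibrate"
        cal = _resolve_calibration(config, dances)
        logger.info("calibration v=%.2f m/s (%s, n=%s)", cal.v, cal.estimator, cal.n)

        stage = "geocode"
        n_night = 0
        for p in phases:
            pos = solar_position(p.timestamp_utc, config.site.lat_deg, config.site.lon_deg)
            if not check_daylight(pos):
                n_night += 1
        if n_night:
            logger.warning("%d phase(s) timestamped with the sun below the horizon", n_night)
        ep_phases = phase_endpoints(phases, config.site, cal)
        ep_dances = dance_endpoints(dances, config.site, cal, estimator=config.estimator)

        stage = "map"
        grid = density_map(
            ep_dances, bandwidth_m=config.bandwidth_m, cell_size_m=config.cell_size_m
        )
        area = search_area(grid, ep_dances, trim_fraction=config.trim_fraction)

        stage = "report"
        times = [p.timestamp_utc for p in phases]
        span_min = (max(times) - min(times)).total_seconds() / 60.0
        if span_min > 0:
            rate = dance_rate(len(dances), span_min)
            rate_val, rate_rounded = rate.per_min, rate.rounded
        else:
            span_min = None
            rate_val = rate_rounded = None
        diag = diagnose(config.site, cal, config.waggle_freq_hz, config.max_signal_hz)
        report = SearchAreaReport(
            n_phases=len(phases),
            n_dances=len(dances),
            calibration_v=cal.v,
            calibration_v_rounded=cal.v_rounded,
            calibration_estimator=cal.estimator,
            calibration_n=cal.n,
            dance_rate_per_min=rate_val,
            dance_rate_rounded=rate_rounded,
            session_span_min=span_min,
            peak_lat=area.peak_lat,
            peak_lon=area.peak_lon,
            circle_center_lat=area.center_lat,
            circle_center_lon=area.center_lon,
            circle_diameter_m=area.diameter_m,
            sector_width_deg=sector_width(
                [e.bearing_deg for e in ep_phases], config.coverage_fraction
            ),
            n_night_phases=n_night,
            **diag,
        )

        stage = "write"
        write_dances(dances, out / "dances.csv")
        write_endpoints_geojson(ep_phases, out / "endpoints_phases.geojson")
        write_endpoints_geojson(ep_dances, out / "endpoints_dances.geojson")
        write_endpoints_csv(ep_phases, out / "endpoints_phases.csv")
        write_endpoints_csv(ep_dances, out / "endpoints_dances.csv")
        write_ascii_grid(grid, out / "density.asc")
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report.model_dump(), fh, sort_keys=True, indent=1)
            fh.write("\n")
        logger.info("wrote artifacts to %s", out)
    except DanceMapError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    except Exception:
        logger.exception("stage %s failed", stage)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    return {
        "report": report.model_dump(),
        "paths": {
            "dances_csv": str(out / "dances.csv"),
            "endpoints_phases_geojson": str(out / "endpoints_phases.geojson"),
            "endpoints_dances_geojson": str(out / "endpoints_dances.geojson"),
            "endpoints_phases_csv": str(out / "endpoints_phases.csv"),
            "endpoints_dances_csv": str(out / "endpoints_dances.csv"),
            "density_asc": str(out / "density.asc"),
            "report_json": str(out / "report.json"),
            "log": str(log_path),
        },
    }


def _config_echo(config: RunConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["site"] = asdict(config.site)
    return d
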