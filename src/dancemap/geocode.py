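"""Dance-to-ground transform: bearings, calibrated distances, endpoint
projection, and sampling/accuracy diagnostics.

The decoded signals of a waggle run are an angle from vertical (stand-in for
the sun's azimuth) and a duration. Geocoding composes them with the solar
ephemeris and a site-estimated *distance calibration factor* ``v`` (meters of
foraging distance per second of waggling, roughly 380 m/s at the study site):

    bearing  = (solar_azimuth + dance_angle) mod 360
    distance = v * duration

and projects the endpoint along that great-circle bearing on a sphere of
radius 6,371 km. Sub-meter ellipsoidal effects are negligible at foraging
ranges (<= 10 km).

Three diagnostics quantify how well the recording samples the signal:

* ``waggle_accuracy`` — ground meters encoded by a single waggle movement,
  ``v / f_waggle`` (about 29 m at 13 Hz);
* ``ring_spacing`` — the ground-distance quantum ``v / fps`` induced by
  frame-quantized durations (about 6 m at 60 fps), visible as concentric
  rings of endpoints;
* ``nyquist_margin`` — ``fps / (2 f_max)``; sampling resolves the waggle
  oscillation iff the margin is at least 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .dances import (
    Dance,
    HiveSite,
    WagglePhase,
    normalize_angle,
    round_half_up,
)
from .errors import CalibrationError, ValidationError
from .solar import solar_position

__all__ = [
    "EARTH_RADIUS_M",
    "CalibrationModel",
    "GeoEndpoint",
    "Quantity",
    "NyquistMargin",
    "bearing_from_dance",
    "distance_from_duration",
    "destination_point",
    "inverse_point",
    "project_endpoint",
    "calibrate",
    "waggle_accuracy",
    "ring_spacing",
    "nyquist_margin",
    "sector_width",
    "phase_endpoints",
    "dance_endpoints",
    "write_endpoints_geojson",
    "read_endpoints_geojson",
    "write_endpoints_csv",
]

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class CalibrationModel:
    """Linear duration-to-distance model ``distance = v * duration``.

    ``v`` is in m/s; ``v_rounded`` reports it to the nearest 10 m/s, the
    precision at which such factors are usually quoted.
    """

    v: float
    estimator: str = "median"
    n: int | None = None

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise CalibrationError(f"calibration factor must be positive, got {self.v}")

    @property
    def v_rounded(self) -> int:
        return 10 * round_half_up(self.v / 10.0)


@dataclass(frozen=True)
class GeoEndpoint:
    """A projected foraging-vector endpoint with its provenance."""

    lat_deg: float
    lon_deg: float
    bearing_deg: float
    distance_m: float
    source_id: str = ""
    kind: str = "dance"  # "phase" or "dance"

    def __post_init__(self) -> None:
        if self.distance_m < 0:
            raise ValidationError(f"distance_m must be >= 0, got {self.distance_m}")
        if not (0.0 <= self.bearing_deg < 360.0):
            raise ValidationError(f"bearing_deg out of range [0, 360): {self.bearing_deg}")
        if self.kind not in ("phase", "dance"):
            raise ValidationError(f"kind must be 'phase' or 'dance', got {self.kind!r}")


class Quantity(NamedTuple):
    """A derived quantity with its rounded (reporting) companion."""

    value: float
    rounded: int


class NyquistMargin(NamedTuple):
    ratio: float
    adequate: bool


def _v_of(calibration) -> float:
    v = calibration.v if isinstance(calibration, CalibrationModel) else float(calibration)
    if v <= 0:
        raise CalibrationError(f"calibration factor must be positive, got {v}")
    return v


def bearing_from_dance(angle_deg: float, solar_azimuth_deg: float) -> float:
    """Compass bearing of the advertised direction.

    The dance angle is measured clockwise from vertical, vertical stands for
    the sun's azimuth, so the bearing is their sum mod 360. Inputs are
    normalized; any finite angles are accepted.
    """
    if not (math.isfinite(angle_deg) and math.isfinite(solar_azimuth_deg)):
        raise ValidationError("angles must be finite")
    return normalize_angle(solar_azimuth_deg + angle_deg)


def distance_from_duration(duration_s: float, calibration: CalibrationModel | float) -> float:
    """Foraging distance ``v * duration`` (linear model)."""
    if duration_s < 0:
        raise ValidationError(f"duration_s must be >= 0, got {duration_s}")
    return _v_of(calibration) * duration_s


def destination_point(
    lat_deg: float, lon_deg: float, bearing_deg: float, distance_m: float
) -> tuple[float, float]:
    """Great-circle destination from a point along an initial bearing."""
    if distance_m == 0.0:
        return float(lat_deg), float(lon_deg)
    phi1 = math.radians(lat_deg)
    lam1 = math.radians(lon_deg)
    theta = math.radians(bearing_deg)
    delta = distance_m / EARTH_RADIUS_M
    sin_phi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    phi2 = math.asin(min(1.0, max(-1.0, sin_phi2)))
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * math.sin(phi2),
    )
    lon2 = math.degrees(lam2)
    lon2 = (lon2 + 180.0) % 360.0 - 180.0
    return math.degrees(phi2), lon2


def inverse_point(
    lat1_deg: float, lon1_deg: float, lat2_deg: float, lon2_deg: float
) -> tuple[float, float]:
    """Great-circle ``(distance_m, initial_bearing_deg)`` between two points."""
    phi1, phi2 = math.radians(lat1_deg), math.radians(lat2_deg)
    dlam = math.radians(lon2_deg - lon1_deg)
    dphi = phi2 - phi1
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    dist = 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))
    y = math.sin(dlam) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlam)
    bearing = normalize_angle(math.degrees(math.atan2(y, x))) if dist > 0 else 0.0
    return dist, bearing


def project_endpoint(
    site: HiveSite,
    bearing_deg: float,
    distance_m: float,
    source_id: str = "",
    kind: str = "dance",
) -> GeoEndpoint:
    """Project a foraging vector from the hive onto the ground."""
    if distance_m < 0:
        raise ValidationError(f"distance_m must be >= 0, got {distance_m}")
    b = normalize_angle(bearing_deg)
    lat, lon = destination_point(site.lat_deg, site.lon_deg, b, distance_m)
    return GeoEndpoint(
        lat_deg=lat, lon_deg=lon, bearing_deg=b, distance_m=distance_m,
        source_id=source_id, kind=kind,
    )


def calibrate(
    durations_s: Sequence[float], known_distance_m: float, estimator: str = "median"
) -> CalibrationModel:
    """Estimate the distance calibration factor from dances to a known feeder.

    ``v = known_distance / estimator(durations)``; the median is the default
    estimator because it is robust to the occasional mis-timed phase.
    """
    durations = np.asarray(list(durations_s), dtype=float)
    if durations.size == 0:
        raise CalibrationError("calibrate requires at least one duration")
    if known_distance_m <= 0:
        raise CalibrationError(f"known_distance_m must be positive, got {known_distance_m}")
    if estimator == "median":
        central = float(np.median(durations))
    elif estimator == "mean":
        central = float(np.mean(durations))
    else:
        raise CalibrationError(f"unknown estimator {estimator!r}")
    if central <= 0:
        raise CalibrationError(f"estimator({estimator}) of durations is not positive: {central}")
    return CalibrationModel(v=known_distance_m / central, estimator=estimator, n=int(durations.size))


def waggle_accuracy(calibration: CalibrationModel | float, waggle_freq_hz: float) -> Quantity:
    """Ground meters encoded by one waggle movement: ``v / f_waggle``."""
    if waggle_freq_hz <= 0:
        raise ValidationError(f"waggle_freq_hz must be positive, got {waggle_freq_hz}")
    value = _v_of(calibration) / waggle_freq_hz
    return Quantity(value, round_half_up(value))


def ring_spacing(calibration: CalibrationModel | float, fps: float) -> Quantity:
    """Ground-distance quantum ``v / fps`` from frame-quantized durations.

    Appears on endpoint maps as concentric curves spaced by this amount.
    """
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    value = _v_of(calibration) / fps
    return Quantity(value, round_half_up(value))


def nyquist_margin(fps: float, max_signal_hz: float) -> NyquistMargin:
    """``fps / (2 f_max)``; the waggle oscillation is resolved iff >= 1."""
    if fps <= 0 or max_signal_hz <= 0:
        raise ValidationError("fps and max_signal_hz must be positive")
    ratio = fps / (2.0 * max_signal_hz)
    return NyquistMargin(ratio, ratio >= 1.0)


def sector_width(bearings_deg: Sequence[float], coverage_fraction: float = 1.0) -> float:
    """Width of the smallest arc containing a fraction of the bearings.

    Exhaustive search over arcs anchored (starting) at observed bearings; the
    optimum of this family equals the global optimum because shrinking any
    covering arc until its start touches a bearing cannot drop a covered
    point. Ties resolve to the smallest width, then the earliest anchor.
    """
    b = sorted(normalize_angle(x) for x in bearings_deg)
    n = len(b)
    if n == 0:
        raise ValidationError("sector_width requires at least one bearing")
    if not (0.0 < coverage_fraction <= 1.0):
        raise ValidationError(f"coverage_fraction must be in (0, 1], got {coverage_fraction}")
    k = max(1, math.ceil(coverage_fraction * n - 1e-12))
    ext = b + [x + 360.0 for x in b]
    best_width = math.inf
    for i in range(n):
        width = ext[i + k - 1] - ext[i]
        if width < best_width - 1e-12:
            best_width = width
    return min(best_width, 360.0)


# ---------------------------------------------------------------------------
# Endpoint batches
# ---------------------------------------------------------------------------

def phase_endpoints(
    phases: Iterable[WagglePhase],
    site: HiveSite,
    calibration: CalibrationModel | float,
) -> list[GeoEndpoint]:
    """One endpoint per waggle phase, using each phase's own angle, duration,
    and solar azimuth (the azimuth drifts a few degrees per 10 minutes at
    midday, so it is evaluated per phase, not per session)."""
    out = []
    for p in phases:
        az = solar_position(p.timestamp_utc, site.lat_deg, site.lon_deg).azimuth_deg
        bearing = bearing_from_dance(p.angle_deg, az)
        dist = distance_from_duration(p.duration_s(site.fps), calibration)
        out.append(
            project_endpoint(site, bearing, dist, source_id=f"{p.dance_id}/{p.phase_index}",
                             kind="phase")
        )
    return out


def dance_endpoints(
    dances: Iterable[Dance],
    site: HiveSite,
    calibration: CalibrationModel | float,
    estimator: str = "median",
) -> list[GeoEndpoint]:
    """One endpoint per dance, from its circular-mean angle and duration
    summary. Dances with an undefined mean direction are rejected."""
    out = []
    for d in dances:
        if d.mean_angle_deg is None:
            raise ValidationError(
                f"dance {d.dance_id}: undefined mean direction (zero resultant length)"
            )
        az = solar_position(d.timestamp_utc, site.lat_deg, site.lon_deg).azimuth_deg
        bearing = bearing_from_dance(d.mean_angle_deg, az)
        dist = distance_from_duration(d.duration_estimate_s(estimator), calibration)
        out.append(project_endpoint(site, bearing, dist, source_id=d.dance_id, kind="dance"))
    return out


# ---------------------------------------------------------------------------
# Endpoint I/O (GeoJSON, WGS84 lon-lat order; mirrored CSV)
# ---------------------------------------------------------------------------

def write_endpoints_geojson(endpoints: Sequence[GeoEndpoint], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [e.lon_deg, e.lat_deg]},
            "properties": {
                "source_id": e.source_id,
                "kind": e.kind,
                "bearing_deg": e.bearing_deg,
                "distance_m": e.distance_m,
            },
        }
        for e in endpoints
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  sort_keys=True, indent=1)
        fh.write("\n")


def read_endpoints_geojson(path) -> list[GeoEndpoint]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for i, feat in enumerate(data.get("features", [])):
        try:
            lon, lat = feat["geometry"]["coordinates"]
            props = feat.get("properties", {})
            out.append(
                GeoEndpoint(
                    lat_deg=float(lat), lon_deg=float(lon),
                    bearing_deg=float(props["bearing_deg"]),
                    distance_m=float(props["distance_m"]),
                    source_id=str(props.get("source_id", "")),
                    kind=str(props.get("kind", "dance")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: feature {i} malformed: {exc}") from exc
    return out


def write_endpoints_csv(endpoints: Sequence[GeoEndpoint], path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "source_id": [e.source_id for e in endpoints],
            "kind": [e.kind for e in endpoints],
            "lat_deg": [repr(e.lat_deg) for e in endpoints],
            "lon_deg": [repr(e.lon_deg) for e in endpoints],
            "bearing_deg": [repr(e.bearing_deg) for e in endpoints],
            "distance_m": [repr(e.distance_m) for e in endpoints],
        }
    )
    df.to_csv(path, index=False)
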