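"""Solar azimuth and elevation at the hive, from the NOAA solar calculator
equations.

Dancers orient their waggle runs relative to gravity, with "up" standing for
the sun's current azimuth. Converting a dance angle into a compass bearing
therefore needs the solar azimuth at the moment of the dance. The equations
here are NOAA's solar-calculator series (Julian century, geometric mean
longitude and anomaly, equation of center, corrected obliquity, equation of
time, hour angle), good to a few hundredths of a degree over 1900-2100 —
orders of magnitude below the dance's intrinsic angular scatter.

Conventions: azimuth in degrees clockwise from *true* north in [0, 360)
(magnetic declination is out of scope); elevation in degrees above the
horizon, with atmospheric refraction applied to the elevation only, never to
the azimuth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

from .errors import ValidationError

__all__ = ["SolarPosition", "solar_position", "check_daylight"]

_D2R = math.pi / 180.0
_R2D = 180.0 / math.pi


@dataclass(frozen=True)
class SolarPosition:
    """Sun direction at an instant: azimuth clockwise from true north,
    refraction-corrected elevation above the horizon."""

    azimuth_deg: float
    elevation_deg: float
    timestamp_utc: datetime

    def __post_init__(self) -> None:
        if not (0.0 <= self.azimuth_deg < 360.0):
            raise ValidationError(f"azimuth out of range [0, 360): {self.azimuth_deg}")
        if not (-90.0 <= self.elevation_deg <= 90.0):
            raise ValidationError(f"elevation out of range [-90, 90]: {self.elevation_deg}")


def _refraction_deg(elevation_deg: float) -> float:
    """NOAA atmospheric refraction correction (degrees) for a true elevation."""
    e = elevation_deg
    if e > 85.0:
        return 0.0
    te = math.tan(e * _D2R)
    if e > 5.0:
        sec = 58.1 / te - 0.07 / te**3 + 0.000086 / te**5
    elif e > -0.575:
        sec = 1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))
    else:
        sec = -20.772 / te
    return sec / 3600.0


def solar_position(timestamp_utc: datetime, lat_deg: float, lon_deg: float) -> SolarPosition:
    """Solar azimuth/elevation at a UTC instant and WGS84 coordinates.

    ``timestamp_utc`` must be timezone-aware; any zone is accepted and
    converted to UTC. Longitude is positive east. Valid for years 1900-2100.
    """
    if not (-90.0 <= lat_deg <= 90.0):
        raise ValidationError(f"lat_deg out of range [-90, 90]: {lat_deg}")
    if not (-180.0 <= lon_deg <= 180.0):
        raise ValidationError(f"lon_deg out of range [-180, 180]: {lon_deg}")
    if not isinstance(timestamp_utc, datetime) or timestamp_utc.tzinfo is None:
        raise ValidationError("timestamp_utc must be a timezone-aware datetime")
    t = timestamp_utc.astimezone(timezone.utc)
    if not (1900 <= t.year <= 2100):
        raise ValidationError(f"timestamp year {t.year} outside supported range 1900-2100")

    jd = t.timestamp() / 86400.0 + 2440587.5
    jc = (jd - 2451545.0) / 36525.0

    # Geometric mean longitude / anomaly of the sun, eccentricity of Earth's orbit
    l0 = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    m = 357.52911 + jc * (35999.05029 - jc * 0.0001537)
    ecc = 0.016708634 - jc * (0.000042037 + jc * 0.0000001267)

    # Equation of center -> true and apparent longitude
    mr = m * _D2R
    c = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + jc * 0.000014))
        + math.sin(2 * mr) * (0.019993 - jc * 0.000101)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = (125.04 - 1934.136 * jc) * _D2R
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)

    # Obliquity (mean + nutation correction) and solar declination
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    decl = math.asin(math.sin(eps * _D2R) * math.sin(app_long * _D2R))

    # Equation of time (minutes)
    y = math.tan(eps * _D2R / 2.0) ** 2
    l0r = l0 * _D2R
    eqtime = 4.0 * _R2D * (
        y * math.sin(2 * l0r)
        - 2.0 * ecc * math.sin(mr)
        + 4.0 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )

    # True solar time -> hour angle (degrees; 0 at solar noon, + afternoon)
    minutes_utc = t.hour * 60.0 + t.minute + t.second / 60.0 + t.microsecond / 6e7
    tst = (minutes_utc + eqtime + 4.0 * lon_deg) % 1440.0
    ha = tst / 4.0 - 180.0
    if ha < -180.0:
        ha += 360.0

    phi = lat_deg * _D2R
    har = ha * _D2R
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(har)
    cos_zen = min(1.0, max(-1.0, cos_zen))
    zen = math.acos(cos_zen)

    sin_zen = math.sin(zen)
    if sin_zen < 1e-12:
        az = 0.0  # sun at zenith/nadir: azimuth degenerate
    else:
        cos_az = (math.sin(phi) * cos_zen - math.sin(decl)) / (math.cos(phi) * sin_zen)
        cos_az = min(1.0, max(-1.0, cos_az))
        az_s = math.acos(cos_az) * _R2D  # angle from south
        az = (az_s + 180.0) % 360.0 if ha > 0 else (540.0 - az_s) % 360.0

    elevation = 90.0 - zen * _R2D
    elevation += _refraction_deg(elevation)
    elevation = min(90.0, max(-90.0, elevation))
    return SolarPosition(azimuth_deg=az, elevation_deg=elevation, timestamp_utc=t)


def check_daylight(position: SolarPosition) -> bool:
    """True iff the sun is strictly above the horizon.

    Dances recorded with the sun at or below the horizon are suspicious
    (timestamp or timezone errors); geocoding warns on them but proceeds.
    """
    return position.elevation_deg > 0.0
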