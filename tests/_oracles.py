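"""Independent oracles used by the tests.

These are deliberately separate derivations from the package's own
implementations: a PSA-series solar ephemeris (vs. the package's NOAA
equations), a 3D vector-algebra great-circle destination (vs. the package's
spherical trigonometry), a brute-force minimal enclosing circle over point
pairs and triples (vs. shapely), and a fine angular grid sweep for the
bearing sector width (vs. the anchored-arc search).
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

import numpy as np


def psa_solar_azimuth_elevation(t: datetime, lat_deg: float, lon_deg: float):
    """PSA ephemeris (Blanco-Muriel et al. 2001): azimuth clockwise from
    north and unrefracted elevation, degrees."""
    t = t.astimezone(timezone.utc)
    hour = t.hour + t.minute / 60.0 + (t.second + t.microsecond / 1e6) / 3600.0
    n = t.timestamp() / 86400.0 - 10957.5  # elapsed Julian days since J2000.0

    omega = 2.1429 - 0.0010394594 * n
    mean_long = 4.8950630 + 0.017202791698 * n
    mean_anom = 6.2400600 + 0.0172019699 * n
    ecl_long = (
        mean_long
        + 0.03341607 * math.sin(mean_anom)
        + 0.00034894 * math.sin(2 * mean_anom)
        - 0.0001134
        - 0.0000203 * math.sin(omega)
    )
    ecl_obliq = 0.4090928 - 6.2140e-9 * n + 0.0000396 * math.cos(omega)

    sin_l = math.sin(ecl_long)
    ra = math.atan2(math.cos(ecl_obliq) * sin_l, math.cos(ecl_long))
    if ra < 0:
        ra += 2 * math.pi
    dec = math.asin(math.sin(ecl_obliq) * sin_l)

    gmst = 6.6974243242 + 0.0657098283 * n + hour
    lmst = math.radians(gmst * 15.0 + lon_deg)
    ha = lmst - ra
    lat = math.radians(lat_deg)

    cos_zen = math.cos(lat) * math.cos(ha) * math.cos(dec) + math.sin(dec) * math.sin(lat)
    zen = math.acos(min(1.0, max(-1.0, cos_zen)))
    az = math.atan2(-math.sin(ha), math.tan(dec) * math.cos(lat) - math.sin(lat) * math.cos(ha))
    az = math.degrees(az) % 360.0
    # parallax correction to zenith
    zen += (6371.01 / 149597890.0) * math.sin(zen)
    return az, 90.0 - math.degrees(zen)


def vector_destination(lat_deg, lon_deg, bearing_deg, distance_m, radius_m=6_371_000.0):
    """Great-circle destination via 3D rotation of the position vector in the
    local east/north frame."""
    phi = math.radians(lat_deg)
    lam = math.radians(lon_deg)
    p = np.array([
        math.cos(phi) * math.cos(lam),
        math.cos(phi) * math.sin(lam),
        math.sin(phi),
    ])
    east = np.array([-math.sin(lam), math.cos(lam), 0.0])
    north = np.cross(p, east)  # right-handed: p x east points to local north
    theta = math.radians(bearing_deg)
    direction = east * math.sin(theta) + north * math.cos(theta)
    delta = distance_m / radius_m
    q = p * math.cos(delta) + direction * math.sin(delta)
    lat2 = math.degrees(math.asin(q[2]))
    lon2 = math.degrees(math.atan2(q[1], q[0]))
    return lat2, lon2


def _circumcircle(a, b, c):
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax * ax + ay * ay) * (by - cy) + (bx * bx + by * by) * (cy - ay)
          + (cx * cx + cy * cy) * (ay - by)) / d
    uy = ((ax * ax + ay * ay) * (cx - bx) + (bx * bx + by * by) * (ax - cx)
          + (cx * cx + cy * cy) * (bx - ax)) / d
    r = math.hypot(ax - ux, ay - uy)
    return ux, uy, r


def brute_force_enclosing_circle(points):
    """Smallest circle containing all points, by exhaustive search over
    circles through point pairs (as diameter) and triples (circumcircle)."""
    pts = [tuple(map(float, p)) for p in points]
    n = len(pts)
    if n == 1:
        return pts[0][0], pts[0][1], 0.0

    def contains(cx, cy, r):
        return all(math.hypot(x - cx, y - cy) <= r + 1e-9 for x, y in pts)

    best = None
    for i in range(n):
        for j in range(i + 1, n):
            cx = (pts[i][0] + pts[j][0]) / 2.0
            cy = (pts[i][1] + pts[j][1]) / 2.0
            r = math.hypot(pts[i][0] - cx, pts[i][1] - cy)
            if contains(cx, cy, r) and (best is None or r < best[2]):
                best = (cx, cy, r)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                cc = _circumcircle(pts[i], pts[j], pts[k])
                if cc and contains(*cc) and (best is None or cc[2] < best[2]):
                    best = cc
    return best


def sweep_sector_width(bearings_deg, coverage_fraction=1.0, step_deg=0.05):
    """Smallest covering-arc width by sweeping candidate arc starts on a fine
    angular grid (plus the exact bearing values)."""
    b = np.sort(np.mod(np.asarray(bearings_deg, dtype=float), 360.0))
    n = len(b)
    k = max(1, math.ceil(coverage_fraction * n - 1e-12))
    anchors = np.concatenate([np.arange(0.0, 360.0, step_deg), b])
    best = 360.0
    for a in anchors:
        offsets = np.sort(np.mod(b - a, 360.0))
        best = min(best, float(offsets[k - 1]))
    return best
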