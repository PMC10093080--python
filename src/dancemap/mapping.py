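"""Endpoint maps: density ("heat map") surfaces, search-area summaries, and
video-annotation geometry (static grid overlay, pixel scale).

All planar geometry runs on a local azimuthal-equidistant tangent plane:
every point is represented by its great-circle distance and bearing from a
reference origin, so x = d sin(bearing), y = d cos(bearing) (meters east and
north). Bearings and distances from the origin are exact in this projection
and distortion is negligible at foraging ranges; results are back-projected
to WGS84 for output.

The density surface is a fixed-bandwidth Gaussian kernel sum over endpoints,
rescaled so the maximum is 100, and summarized by contour thresholds
(0, 20, 40, 60, 80, 98, 100 percent by default). The search area is the
density peak plus the minimal enclosing circle of the (optionally trimmed)
endpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point

from .errors import ValidationError
from .geocode import GeoEndpoint, destination_point, inverse_point, normalize_angle

__all__ = [
    "DensityGrid",
    "SearchArea",
    "to_local",
    "to_geo",
    "density_map",
    "search_area",
    "minimal_enclosing_circle",
    "grid_overlay",
    "pixel_scale",
    "object_px",
    "write_ascii_grid",
    "render_density",
]

DEFAULT_PALETTE = (0.0, 20.0, 40.0, 60.0, 80.0, 98.0, 100.0)


def to_local(lat_deg: float, lon_deg: float, origin_lat: float, origin_lon: float) -> tuple[float, float]:
    """Project to the azimuthal-equidistant tangent plane at the origin:
    (x east, y north) in meters."""
    d, b = inverse_point(origin_lat, origin_lon, lat_deg, lon_deg)
    br = math.radians(b)
    return d * math.sin(br), d * math.cos(br)


def to_geo(x_m: float, y_m: float, origin_lat: float, origin_lon: float) -> tuple[float, float]:
    """Inverse of :func:`to_local`."""
    d = math.hypot(x_m, y_m)
    if d == 0.0:
        return origin_lat, origin_lon
    b = normalize_angle(math.degrees(math.atan2(x_m, y_m)))
    return destination_point(origin_lat, origin_lon, b, d)


@dataclass
class DensityGrid:
    """Regular tangent-plane grid of endpoint density, max-normalized to 100.

    ``values[iy, ix]`` is the density at the cell center
    ``(x_min + (ix + 0.5) * cell, y_min + (iy + 0.5) * cell)`` in local meters
    relative to ``(origin_lat, origin_lon)``; y grows northward.
    """

    origin_lat: float
    origin_lon: float
    x_min: float
    y_min: float
    cell_size_m: float
    values: np.ndarray
    bandwidth_m: float
    palette_thresholds: tuple[float, ...] = DEFAULT_PALETTE

    @property
    def n_x(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_y(self) -> int:
        return int(self.values.shape[0])

    def cell_center_local(self, ix: int, iy: int) -> tuple[float, float]:
        return (
            self.x_min + (ix + 0.5) * self.cell_size_m,
            self.y_min + (iy + 0.5) * self.cell_size_m,
        )

    def cell_center_geo(self, ix: int, iy: int) -> tuple[float, float]:
        x, y = self.cell_center_local(ix, iy)
        return to_geo(x, y, self.origin_lat, self.origin_lon)


@dataclass(frozen=True)
class SearchArea:
    """Density peak plus minimal enclosing circle of the used endpoints."""

    peak_lat: float
    peak_lon: float
    center_lat: float
    center_lon: float
    diameter_m: float
    n_endpoints: int

    def __post_init__(self) -> None:
        if self.diameter_m < 0:
            raise ValidationError("diameter_m must be >= 0")


def _local_coords(
    endpoints: Sequence[GeoEndpoint], origin_lat: float, origin_lon: float
) -> np.ndarray:
    return np.array(
        [to_local(e.lat_deg, e.lon_deg, origin_lat, origin_lon) for e in endpoints]
    )


def density_map(
    endpoints: Sequence[GeoEndpoint],
    bandwidth_m: float = 29.0,
    cell_size_m: float = 5.0,
    origin: tuple[float, float] | None = None,
    palette_thresholds: Sequence[float] = DEFAULT_PALETTE,
) -> DensityGrid:
    """Gaussian kernel density of endpoints on a tangent-plane grid.

    The kernel is isotropic with sigma = ``bandwidth_m`` (default 29 m, the
    one-waggle ground accuracy at v = 380 m/s and 13 Hz, so the smoothing
    scale matches the signal's intrinsic resolution). The grid covers all
    endpoints plus a two-bandwidth margin and is rescaled so its maximum cell
    is 100. ``origin`` defaults to the endpoint centroid, which makes the
    surface invariant under rigid translation of the swarm of endpoints.
    """
    if len(endpoints) == 0:
        raise ValidationError("density_map requires at least one endpoint")
    if bandwidth_m <= 0 or cell_size_m <= 0:
        raise ValidationError("bandwidth_m and cell_size_m must be positive")
    if origin is None:
        origin = (
            float(np.mean([e.lat_deg for e in endpoints])),
            float(np.mean([e.lon_deg for e in endpoints])),
        )
    pts = _local_coords(endpoints, *origin)
    margin = 2.0 * bandwidth_m
    x_min = float(pts[:, 0].min()) - margin
    x_max = float(pts[:, 0].max()) + margin
    y_min = float(pts[:, 1].min()) - margin
    y_max = float(pts[:, 1].max()) + margin
    n_x = max(1, int(math.ceil((x_max - x_min) / cell_size_m)))
    n_y = max(1, int(math.ceil((y_max - y_min) / cell_size_m)))

    xc = x_min + (np.arange(n_x) + 0.5) * cell_size_m
    yc = y_min + (np.arange(n_y) + 0.5) * cell_size_m
    inv2s2 = 1.0 / (2.0 * bandwidth_m * bandwidth_m)
    # separable kernel: sum_k exp(-dx^2) * exp(-dy^2) via outer products
    values = np.zeros((n_y, n_x))
    for chunk in np.array_split(pts, max(1, len(pts) // 512 + 1)):
        gx = np.exp(-((xc[None, :] - chunk[:, 0][:, None]) ** 2) * inv2s2)
        gy = np.exp(-((yc[None, :] - chunk[:, 1][:, None]) ** 2) * inv2s2)
        values += np.einsum("ky,kx->yx", gy, gx)
    peak = values.max()
    if peak > 0:
        values *= 100.0 / peak
    return DensityGrid(
        origin_lat=origin[0],
        origin_lon=origin[1],
        x_min=x_min,
        y_min=y_min,
        cell_size_m=cell_size_m,
        values=values,
        bandwidth_m=bandwidth_m,
        palette_thresholds=tuple(float(t) for t in palette_thresholds),
    )


def minimal_enclosing_circle(points_xy: np.ndarray) -> tuple[float, float, float]:
    """Minimal enclosing circle ``(cx, cy, radius)`` of planar points."""
    points_xy = np.asarray(points_xy, dtype=float)
    if len(points_xy) == 0:
        raise ValidationError("minimal_enclosing_circle requires at least one point")
    if len(points_xy) == 1:
        return float(points_xy[0, 0]), float(points_xy[0, 1]), 0.0
    mp = MultiPoint([Point(xy) for xy in points_xy])
    radius = float(shapely.minimum_bounding_radius(mp))
    if radius == 0.0:  # all points coincide; shapely returns an empty polygon
        return float(points_xy[0, 0]), float(points_xy[0, 1]), 0.0
    circle = shapely.minimum_bounding_circle(mp)
    minx, miny, maxx, maxy = circle.bounds
    return (minx + maxx) / 2.0, (miny + maxy) / 2.0, radius


def search_area(
    grid: DensityGrid,
    endpoints: Sequence[GeoEndpoint],
    trim_fraction: float = 0.0,
) -> SearchArea:
    """Summarize the search area advertised by the endpoints.

    Peak = center of the grid's argmax cell (ties resolve to the cell closest
    to the endpoint centroid, then to the lowest index). The enclosing circle
    is the minimal enclosing circle of the endpoints after discarding the
    ``trim_fraction`` farthest from the peak (default 0: a conservative bound
    containing every endpoint).
    """
    if len(endpoints) == 0:
        raise ValidationError("search_area requires at least one endpoint")
    if not (0.0 <= trim_fraction < 1.0):
        raise ValidationError(f"trim_fraction must be in [0, 1), got {trim_fraction}")
    pts = _local_coords(endpoints, grid.origin_lat, grid.origin_lon)
    centroid = pts.mean(axis=0)

    vmax = grid.values.max()
    iy_all, ix_all = np.nonzero(grid.values >= vmax - 1e-9)
    centers = np.array(
        [grid.cell_center_local(ix, iy) for ix, iy in zip(ix_all, iy_all)]
    )
    d_centroid = np.hypot(centers[:, 0] - centroid[0], centers[:, 1] - centroid[1])
    best = int(np.argmin(d_centroid))  # argmin keeps the lowest index on ties
    peak_xy = centers[best]
    peak_lat, peak_lon = to_geo(peak_xy[0], peak_xy[1], grid.origin_lat, grid.origin_lon)

    d_peak = np.hypot(pts[:, 0] - peak_xy[0], pts[:, 1] - peak_xy[1])
    n_drop = int(math.floor(trim_fraction * len(pts)))
    keep_idx = np.argsort(d_peak, kind="stable")[: len(pts) - n_drop]
    kept = pts[np.sort(keep_idx)]

    cx, cy, radius = minimal_enclosing_circle(kept)
    # containment sanity: every kept endpoint inside, 1 cm tolerance
    d = np.hypot(kept[:, 0] - cx, kept[:, 1] - cy)
    if d.max() > radius + 0.01:
        raise ValidationError(
            f"enclosing circle misses an endpoint by {d.max() - radius:.3f} m"
        )
    center_lat, center_lon = to_geo(cx, cy, grid.origin_lat, grid.origin_lon)
    return SearchArea(
        peak_lat=peak_lat,
        peak_lon=peak_lon,
        center_lat=center_lat,
        center_lon=center_lon,
        diameter_m=2.0 * radius,
        n_endpoints=int(len(kept)),
    )


# ---------------------------------------------------------------------------
# Video annotation geometry
# ---------------------------------------------------------------------------

def grid_overlay(video_w_px: int, video_h_px: int, cell_px: int) -> tuple[list[int], list[int]]:
    """Static grid line positions for video annotation.

    Returns ``(vertical_x, horizontal_y)``: vertical lines at x = k*cell_px
    strictly inside the frame (k >= 1), likewise horizontal. A cell size at
    least the frame size simply yields empty lists.
    """
    if video_w_px <= 0 or video_h_px <= 0 or cell_px <= 0:
        raise ValidationError("grid_overlay arguments must be positive integers")
    xs = list(range(cell_px, video_w_px, cell_px))
    ys = list(range(cell_px, video_h_px, cell_px))
    return xs, ys


def pixel_scale(px_extent: float, mm_extent: float) -> float:
    """Spatial resolution in pixels per millimeter."""
    if px_extent <= 0 or mm_extent <= 0:
        raise ValidationError("extents must be positive")
    return px_extent / mm_extent


def object_px(size_mm: float, scale_px_per_mm: float) -> int:
    """On-screen size in pixels of an object of known physical size."""
    if size_mm <= 0 or scale_px_per_mm <= 0:
        raise ValidationError("size and scale must be positive")
    from .dances import round_half_up

    return round_half_up(size_mm * scale_px_per_mm)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: DensityGrid, path) -> None:
    """Write the density grid as an ESRI ASCII grid (.asc) in the local
    metric tangent-plane CRS; the header comments record the geographic
    origin so the grid can be georeferenced (see README)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_x}\n")
        fh.write(f"nrows {grid.n_y}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size_m!r}\n")
        fh.write("NODATA_value -9999\n")
        # ASCII grid rows run north to south
        for row in grid.values[::-1]:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def render_density(grid: DensityGrid, path, endpoints: Sequence[GeoEndpoint] | None = None) -> None:
    """Optional PNG rendering of the density surface (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    extent = (
        grid.x_min,
        grid.x_min + grid.n_x * grid.cell_size_m,
        grid.y_min,
        grid.y_min + grid.n_y * grid.cell_size_m,
    )
    ax.imshow(grid.values, origin="lower", extent=extent, cmap="inferno")
    ax.contour(grid.values, levels=[t for t in grid.palette_thresholds if 0 < t < 100],
               origin="lower", extent=extent, colors="w", linewidths=0.6)
    if endpoints:
        pts = _local_coords(endpoints, grid.origin_lat, grid.origin_lon)
        ax.plot(pts[:, 0], pts[:, 1], ".", ms=2, color="cyan")
    ax.set_xlabel("east of origin (m)")
    ax.set_ylabel("north of origin (m)")
    fig.savefig(path, dpi=150)
    plt.close(fig)
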