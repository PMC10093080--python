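"""Waggle-phase and dance domain types, frame-time arithmetic, and CSV I/O.

A *waggle phase* is one straight run of the figure-eight waggle dance. On the
vertical comb the run's angle from "up" stands for the horizontal angle between
the sun's azimuth and the food source, and the run's duration encodes the
distance. Phases are timed in whole video frames, so a duration is always an
integer multiple of ``1/fps``; that quantum is what later produces the
concentric "ring" pattern in endpoint maps.

A *dance* groups the phases of one bout: its direction signal is the circular
(vector-sum) mean of the phase angles and its distance signal is a duration
summary (median by default, written ``eta`` in the field's tables, alongside
mean ``mu`` and standard deviation ``sigma``).

Angle convention: degrees in [0, 360), measured clockwise from vertical, so
that adding the solar azimuth yields a compass bearing. Timestamps are stored
timezone-aware in UTC; local wall-clock times must be converted on ingest
(solar geometry needs unambiguous time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "WagglePhase",
    "Dance",
    "HiveSite",
    "DanceRate",
    "normalize_angle",
    "circular_mean",
    "circular_difference",
    "duration_from_frames",
    "phases_to_dances",
    "dance_rate",
    "read_phases",
    "write_phases",
    "write_dances",
    "round_half_up",
]

#: columns required in a phase CSV, in canonical order
PHASE_COLUMNS = [
    "dance_id",
    "phase_index",
    "frame_start",
    "frame_end",
    "angle_deg",
    "timestamp_utc",
]

DANCE_COLUMNS = [
    "dance_id",
    "n_phases",
    "mean_angle_deg",
    "duration_median_s",
    "duration_mean_s",
    "duration_sd_s",
    "timestamp_utc",
]

#: resultant lengths below this are treated as "no preferred direction"
_RESULTANT_EPS = 1e-9


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    Used for every human-facing "rounded companion" value so results do not
    depend on banker's rounding.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def normalize_angle(angle_deg: float) -> float:
    """Wrap an angle in degrees into [0, 360)."""
    a = math.fmod(float(angle_deg), 360.0)
    if a < 0.0:
        a += 360.0
    return 0.0 if a == 360.0 else a


def circular_difference(a_deg: float, b_deg: float) -> float:
    """Signed smallest rotation from ``b`` to ``a``, in (-180, 180]."""
    d = math.fmod(float(a_deg) - float(b_deg), 360.0)
    if d <= -180.0:
        d += 360.0
    elif d > 180.0:
        d -= 360.0
    return d


def circular_mean(angles_deg: Sequence[float]) -> tuple[float | None, float]:
    """Vector-sum circular mean of angles in degrees.

    Returns ``(mean_deg, resultant_length)``. The mean is the atan2 of the
    mean sine and cosine, in [0, 360). When the mean resultant length is
    numerically zero (e.g. two antipodal angles) the direction is undefined
    and ``None`` is returned instead of an arbitrary angle.
    """
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        raise ValidationError("circular_mean requires at least one angle")
    s = float(np.mean(np.sin(a)))
    c = float(np.mean(np.cos(a)))
    r = math.hypot(s, c)
    if r < _RESULTANT_EPS:
        return None, r
    return normalize_angle(math.degrees(math.atan2(s, c))), r


def duration_from_frames(frame_start: int, frame_end: int, fps: float) -> float:
    """Phase duration in seconds from start/end frame indices.

    ``(frame_end - frame_start) / fps`` — always an exact multiple of the
    frame period ``1/fps``.
    """
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    if frame_end <= frame_start:
        raise ValidationError(
            f"frame_end ({frame_end}) must be strictly after frame_start ({frame_start})"
        )
    return (frame_end - frame_start) / fps


def _ensure_utc(ts: datetime, context: str = "timestamp") -> datetime:
    if not isinstance(ts, datetime) or ts.tzinfo is None:
        raise ValidationError(f"{context} must be a timezone-aware datetime, got {ts!r}")
    return ts.astimezone(timezone.utc)


@dataclass(frozen=True)
class WagglePhase:
    """One waggle run: frame-timed duration plus angle from vertical."""

    dance_id: str
    phase_index: int
    frame_start: int
    frame_end: int
    angle_deg: float
    timestamp_utc: datetime

    def __post_init__(self) -> None:
        if self.phase_index < 0:
            raise ValidationError(f"phase_index must be >= 0, got {self.phase_index}")
        if self.frame_end <= self.frame_start:
            raise ValidationError(
                f"phase {self.dance_id}/{self.phase_index}: frame_end ({self.frame_end}) "
                f"must be strictly after frame_start ({self.frame_start})"
            )
        if not (0.0 <= self.angle_deg < 360.0):
            raise ValidationError(
                f"phase {self.dance_id}/{self.phase_index}: angle_deg must be in "
                f"[0, 360), got {self.angle_deg}"
            )
        object.__setattr__(
            self, "timestamp_utc", _ensure_utc(self.timestamp_utc, "timestamp_utc")
        )

    def duration_s(self, fps: float) -> float:
        return duration_from_frames(self.frame_start, self.frame_end, fps)


@dataclass(frozen=True)
class HiveSite:
    """Geographic and optical context of a recording hive.

    ``frame_inner_width_mm`` is the inner width of the comb frame imaged by
    the camera (410 mm for the standard deep frame used here); it anchors the
    pixel-scale geometry.
    """

    lat_deg: float
    lon_deg: float
    fps: float = 60.0
    utc_offset_h: float = 0.0
    frame_inner_width_mm: float = 410.0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_deg <= 90.0):
            raise ValidationError(f"lat_deg out of range [-90, 90]: {self.lat_deg}")
        if not (-180.0 <= self.lon_deg <= 180.0):
            raise ValidationError(f"lon_deg out of range [-180, 180]: {self.lon_deg}")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.frame_inner_width_mm <= 0:
            raise ValidationError("frame_inner_width_mm must be positive")


@dataclass(frozen=True)
class Dance:
    """A grouped dance bout with circular-mean angle and duration statistics.

    ``mean_angle_deg`` is ``None`` when the phase angles have no preferred
    direction (mean resultant length numerically zero); downstream geocoding
    refuses such dances rather than projecting an arbitrary bearing.
    """

    dance_id: str
    phases: tuple[WagglePhase, ...]
    mean_angle_deg: float | None
    resultant_length: float
    duration_median_s: float
    duration_mean_s: float
    duration_sd_s: float
    timestamp_utc: datetime

    def __post_init__(self) -> None:
        if len(self.phases) < 1:
            raise ValidationError(f"dance {self.dance_id} must contain at least one phase")
        if self.mean_angle_deg is not None and not (0.0 <= self.mean_angle_deg < 360.0):
            raise ValidationError(f"mean_angle_deg out of range: {self.mean_angle_deg}")
        if self.duration_median_s < 0:
            raise ValidationError("duration_median_s must be >= 0")
        object.__setattr__(
            self, "timestamp_utc", _ensure_utc(self.timestamp_utc, "timestamp_utc")
        )

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def duration_estimate_s(self, estimator: str = "median") -> float:
        """Duration summary used for distance decoding (``median`` or ``mean``)."""
        if estimator == "median":
            return self.duration_median_s
        if estimator == "mean":
            return self.duration_mean_s
        raise ValidationError(f"unknown duration estimator {estimator!r}")

    @classmethod
    def from_phases(cls, dance_id: str, phases: Sequence[WagglePhase], fps: float) -> "Dance":
        ordered = tuple(sorted(phases, key=lambda p: p.phase_index))
        seen: set[int] = set()
        for p in ordered:
            if p.phase_index in seen:
                raise ValidationError(
                    f"dance {dance_id}: duplicated phase_index {p.phase_index}"
                )
            seen.add(p.phase_index)
        durations = np.array([p.duration_s(fps) for p in ordered])
        mean_angle, r = circular_mean([p.angle_deg for p in ordered])
        sd = float(np.std(durations, ddof=1)) if durations.size > 1 else 0.0
        return cls(
            dance_id=dance_id,
            phases=ordered,
            mean_angle_deg=mean_angle,
            resultant_length=r,
            duration_median_s=float(np.median(durations)),
            duration_mean_s=float(np.mean(durations)),
            duration_sd_s=sd,
            timestamp_utc=ordered[0].timestamp_utc,
        )


def phases_to_dances(phases: Iterable[WagglePhase], fps: float) -> list[Dance]:
    """Group phases by dance id into Dance records.

    Dances are returned in order of first appearance of their id. Duplicated
    ``(dance_id, phase_index)`` pairs raise :class:`ValidationError`. The
    total phase count is conserved.
    """
    groups: dict[str, list[WagglePhase]] = {}
    for p in phases:
        groups.setdefault(p.dance_id, []).append(p)
    return [Dance.from_phases(did, ps, fps) for did, ps in groups.items()]


class DanceRate(NamedTuple):
    """Dance rate in dances per minute, with its rounded companion."""

    per_min: float
    rounded: int


def dance_rate(n_dances: int, duration_min: float) -> DanceRate:
    """Dances per minute over an observation window."""
    if duration_min <= 0:
        raise ValidationError(f"duration_min must be positive, got {duration_min}")
    if n_dances < 0:
        raise ValidationError("n_dances must be >= 0")
    rate = n_dances / duration_min
    return DanceRate(rate, round_half_up(rate))


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_phases(path) -> list[WagglePhase]:
    """Read a phase CSV (UTF-8, header required).

    Columns: ``dance_id,phase_index,frame_start,frame_end,angle_deg,
    timestamp_utc`` with ISO-8601 timestamps. Malformed rows are collected and
    reported together with their 1-based line numbers; a header-only file
    yields an empty list.
    """
    try:
        df = pd.read_csv(path, dtype={"dance_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file, header required") from exc
    missing = [c for c in PHASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")

    phases: list[WagglePhase] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # 1-based, after the header line
        try:
            ts = pd.Timestamp(row["timestamp_utc"])
            if ts.tzinfo is None:
                raise ValueError("timestamp lacks a UTC offset")
            phases.append(
                WagglePhase(
                    dance_id=str(row["dance_id"]),
                    phase_index=int(row["phase_index"]),
                    frame_start=int(row["frame_start"]),
                    frame_end=int(row["frame_end"]),
                    angle_deg=float(row["angle_deg"]),
                    timestamp_utc=ts.to_pydatetime(),
                )
            )
        except (ValidationError, ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise ValidationError(f"{path}: {len(problems)} invalid row(s)\n" + "\n".join(problems))
    return phases


def write_phases(phases: Sequence[WagglePhase], path) -> None:
    """Write phases to CSV; ``read_phases(write_phases(x)) == x``."""
    df = pd.DataFrame(
        {
            "dance_id": [p.dance_id for p in phases],
            "phase_index": [p.phase_index for p in phases],
            "frame_start": [p.frame_start for p in phases],
            "frame_end": [p.frame_end for p in phases],
            "angle_deg": [repr(p.angle_deg) for p in phases],
            "timestamp_utc": [p.timestamp_utc.isoformat() for p in phases],
        },
        columns=PHASE_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_dances(dances: Sequence[Dance], path) -> None:
    """Write per-dance summary rows (see :data:`DANCE_COLUMNS`)."""
    df = pd.DataFrame(
        {
            "dance_id": [d.dance_id for d in dances],
            "n_phases": [d.n_phases for d in dances],
            "mean_angle_deg": [
                "" if d.mean_angle_deg is None else repr(d.mean_angle_deg) for d in dances
            ],
            "duration_median_s": [repr(d.duration_median_s) for d in dances],
            "duration_mean_s": [repr(d.duration_mean_s) for d in dances],
            "duration_sd_s": [repr(d.duration_sd_s) for d in dances],
            "timestamp_utc": [d.timestamp_utc.isoformat() for d in dances],
        },
        columns=DANCE_COLUMNS,
    )
    df.to_csv(path, index=False)
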