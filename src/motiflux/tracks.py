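"""Data model and motility metrics for intravital cell tracks.

A *track* is the timed 2-D trajectory of one cell inside one imaging field
of view (FOV), as exported by tracking software (e.g. spot/manual tracking
of maximum-intensity-projection movies).  From each track four scalar
metrics are derived:

* **track duration** — time span between the first and last observation;
* **total displacement** — summed Euclidean step lengths (path length);
* **net displacement** — straight-line distance from first to last point;
* **track speed mean** — path length divided by duration, i.e. the
  duration-weighted mean of per-step speeds, robust to dropped frames.

Coordinates are planar micrometres; time is seconds from movie start.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRACK_TABLE_COLUMNS = ["fov_id", "track_id", "t_s", "x_um", "y_um"]


class UndefinedMetricError(ValueError):
    """Raised when a metric needs >=2 points but the track has one."""


@dataclass(frozen=True)
class TrackPoint:
    """One timed observation of a cell: time in seconds, position in μm."""

    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t) and math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite track point (t={self.t}, x={self.x}, y={self.y})")
        if self.t < 0:
            raise ValueError(f"negative timestamp {self.t}")


@dataclass(frozen=True)
class Track:
    """Ordered trajectory of one cell in one field of view.

    Invariants: at least one point; strictly increasing timestamps.
    """

    fov_id: str
    track_id: str
    points: tuple[TrackPoint, ...]

    def __post_init__(self) -> None:
        pts = tuple(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) == 0:
            raise ValueError(f"track {self.fov_id}/{self.track_id} has no points")
        times = [p.t for p in pts]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"track {self.fov_id}/{self.track_id} timestamps not strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of positions in μm."""
        return np.array([[p.x, p.y] for p in self.points], dtype=float)


@dataclass(frozen=True)
class TrackMetrics:
    """Per-track motility metrics; all non-negative, net <= total."""

    duration_s: float
    speed_mean_um_per_s: float
    net_displacement_um: float
    total_displacement_um: float

    def __post_init__(self) -> None:
        vals = (
            self.duration_s,
            self.speed_mean_um_per_s,
            self.net_displacement_um,
            self.total_displacement_um,
        )
        if any(not math.isfinite(v) or v < 0 for v in vals):
            raise ValueError(f"metrics must be finite and non-negative: {self}")
        # small slack for accumulated floating error in long paths
        if self.net_displacement_um > self.total_displacement_um * (1 + 1e-9) + 1e-12:
            raise ValueError("net displacement exceeds total displacement")


@dataclass
class Movie:
    """A field of view: its extent, duration and the tracks recorded in it."""

    fov_id: str
    duration_s: float
    width_um: float
    height_um: float
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("movie duration and extent must be positive")
        for tr in self.tracks:
            for p in tr.points:
                if not (0 <= p.t <= self.duration_s):
                    raise ValueError(f"track {tr.track_id} time {p.t} outside movie")
                if not (0 <= p.x <= self.width_um and 0 <= p.y <= self.height_um):
                    raise ValueError(f"track {tr.track_id} position outside field of view")


def track_duration(track: Track) -> float:
    """Time span of a track in seconds; 0 for a single-point track."""
    return float(track.points[-1].t - track.points[0].t)


def total_displacement(track: Track) -> float:
    """Path length: sum of Euclidean step lengths, in μm."""
    xy = track.xy
    if len(xy) < 2:
        return 0.0
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def net_displacement(track: Track) -> float:
    """Straight-line distance between the first and last point, in μm."""
    xy = track.xy
    return float(np.hypot(*(xy[-1] - xy[0])))


def track_speed_mean(track: Track) -> float:
    """Mean speed = path length / duration (duration-weighted step speed).

    Raises :class:`UndefinedMetricError` for single-point tracks.
    """
    if len(track) < 2:
        raise UndefinedMetricError(
            f"track {track.fov_id}/{track.track_id}: speed undefined for a single point"
        )
    return total_displacement(track) / track_duration(track)


def compute_metrics(track: Track) -> TrackMetrics:
    """Bundle duration, mean speed, net and total displacement for one track."""
    speed = track_speed_mean(track)  # raises for single-point tracks
    return TrackMetrics(
        duration_s=track_duration(track),
        speed_mean_um_per_s=speed,
        net_displacement_um=net_displacement(track),
        total_displacement_um=total_displacement(track),
    )


# ---------------------------------------------------------------------------
# Track-table I/O
# ---------------------------------------------------------------------------

def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Flatten tracks into the canonical long table."""
    rows = [
        (tr.fov_id, tr.track_id, p.t, p.x, p.y)
        for tr in tracks
        for p in tr.points
    ]
    return pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Build validated :class:`Track` objects from a long table.

    Rows are sorted by time within each (fov_id, track_id) group; duplicate
    timestamps within one track raise ``ValueError``.
    """
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    if "z_um" in df.columns:
        warnings.warn(
            "track table has a z_um column; planar metrics ignore it",
            stacklevel=2,
        )
    tracks = []
    for (fov, tid), grp in df.groupby(["fov_id", "track_id"], sort=True):
        grp = grp.sort_values("t_s")
        tvals = grp["t_s"].to_numpy(dtype=float)
        if len(np.unique(tvals)) != len(tvals):
            raise ValueError(f"duplicate timestamps in track {fov}/{tid}")
        pts = tuple(
            TrackPoint(t=float(t), x=float(x), y=float(y))
            for t, x, y in zip(tvals, grp["x_um"], grp["y_um"])
        )
        tracks.append(Track(fov_id=str(fov), track_id=str(tid), points=pts))
    return tracks


def read_track_table(
    path: str | Path,
    sep: str = ",",
    frame_interval_s: float | None = None,
) -> list[Track]:
    """Read a delimited track table.

    Expected header: ``fov_id,track_id,t_s,x_um,y_um[,z_um]``.  If the file
    carries a ``frame`` column instead of ``t_s``, `frame_interval_s` must be
    given and timestamps are ``frame * frame_interval_s``.
    """
    df = pd.read_csv(path, sep=sep)
    if "t_s" not in df.columns:
        if "frame" not in df.columns or frame_interval_s is None:
            raise ValueError(
                "track table has no t_s column; provide a frame column and "
                "frame_interval_s to convert frame indices to seconds"
            )
        df = df.assign(t_s=df["frame"].astype(float) * float(frame_interval_s))
    return frame_to_tracks(df)


def write_track_table(tracks: Sequence[Track], path: str | Path, sep: str = ",") -> None:
    """Write tracks in the same dialect :func:`read_track_table` accepts."""
    tracks_to_frame(tracks).to_csv(path, sep=sep, index=False)


def split_single_point_tracks(tracks: Sequence[Track]) -> tuple[list[Track], list[Track]]:
    """Separate classifiable (>=2 points) from single-point tracks.

    Single-point tracks are retained by readers but excluded from metric and
    classification stages; the count is logged.
    """
    usable = [t for t in tracks if len(t) >= 2]
    dropped = [t for t in tracks if len(t) < 2]
    if dropped:
        logger.info("excluding %d single-point track(s) from metric stages", len(dropped))
    return usable, dropped
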