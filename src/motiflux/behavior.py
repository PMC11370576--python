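"""Rule-based leukocyte behavior classification.

Each track is assigned exactly one of four behaviors from its duration and
mean speed, mirroring how intravital neutrophil movies are scored per field
of view:

* **tethering** — brief capture and release: duration under the short cut
  (default 150 s);
* **adherent** — arrested: longer-lived but mean speed at or below the speed
  cut (default 0.03 μm/s);
* **crawling** — motile and persistent: faster than the cut with duration at
  or above the long cut (default 600 s, half of a 20-min movie);
* **patrolling** — motile transit of the field of view: faster than the cut
  with intermediate duration.

Boundary conventions (the published rules leave equalities open): duration
exactly at the short cut is *not* tethering; speed exactly at the cut is
adherent; duration exactly at the long cut is crawling.  The decision tree
below is total — every (duration, speed) pair gets exactly one class.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .tracks import (
    Track,
    TrackMetrics,
    compute_metrics,
    split_single_point_tracks,
)


class BehaviorClass(str, Enum):
    """The four per-track behaviors."""

    TETHERING = "tethering"
    ADHERENT = "adherent"
    CRAWLING = "crawling"
    PATROLLING = "patrolling"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


BEHAVIOR_ORDER = (
    BehaviorClass.ADHERENT,
    BehaviorClass.CRAWLING,
    BehaviorClass.PATROLLING,
    BehaviorClass.TETHERING,
)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Duration/speed cut-offs of the behavior rules.

    Defaults match a 20-minute neutrophil movie; for a 1-hour movie pass
    ``long_duration_s=1800`` (half the video).
    """

    speed_cut_um_per_s: float = 0.03
    short_duration_s: float = 150.0
    long_duration_s: float = 600.0

    def __post_init__(self) -> None:
        if self.speed_cut_um_per_s <= 0:
            raise ValueError("speed cut must be positive")
        if not (0 < self.short_duration_s < self.long_duration_s):
            raise ValueError("need 0 < short_duration_s < long_duration_s")


@dataclass(frozen=True)
class FovBehaviorSummary:
    """Per-FOV class counts and frequencies over classifiable tracks."""

    fov_id: str
    counts: dict[BehaviorClass, int]
    frequencies: dict[BehaviorClass, float]
    n_tracks: int
    n_excluded_single_point: int = 0

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_tracks:
            raise ValueError("counts do not sum to the number of classified tracks")
        if self.n_tracks > 0 and abs(sum(self.frequencies.values()) - 1.0) > 1e-9:
            raise ValueError("frequencies do not sum to 1")


class EmptySummaryError(ValueError):
    """Raised when a FOV has no classifiable track."""


def classify_behavior(
    metrics: TrackMetrics,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> BehaviorClass:
    """Assign one behavior class from duration and mean speed.

    Evaluation order: tethering -> adherent -> crawling -> patrolling.
    """
    d = metrics.duration_s
    s = metrics.speed_mean_um_per_s
    if d < thresholds.short_duration_s:
        return BehaviorClass.TETHERING
    if s <= thresholds.speed_cut_um_per_s:
        return BehaviorClass.ADHERENT
    if d >= thresholds.long_duration_s:
        return BehaviorClass.CRAWLING
    return BehaviorClass.PATROLLING


def classify_tracks(
    tracks: Sequence[Track],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """Compute metrics and behavior for every classifiable track.

    Returns the per-track classification table with columns
    ``fov_id, track_id, duration_s, speed_mean_um_per_s, net_um, total_um,
    behavior``.  Single-point tracks are excluded.
    """
    usable, _ = split_single_point_tracks(tracks)
    rows = []
    for tr in usable:
        m = compute_metrics(tr)
        rows.append(
            (
                tr.fov_id,
                tr.track_id,
                m.duration_s,
                m.speed_mean_um_per_s,
                m.net_displacement_um,
                m.total_displacement_um,
                classify_behavior(m, thresholds).value,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "fov_id",
            "track_id",
            "duration_s",
            "speed_mean_um_per_s",
            "net_um",
            "total_um",
            "behavior",
        ],
    )


def summarize_fov(
    tracks: Sequence[Track],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> FovBehaviorSummary:
    """Count and normalize behavior classes for the tracks of one FOV."""
    fovs = {t.fov_id for t in tracks}
    if len(fovs) != 1:
        raise ValueError(f"summarize_fov needs tracks from exactly one FOV, got {sorted(fovs)}")
    fov_id = fovs.pop()
    usable, dropped = split_single_point_tracks(tracks)
    if not usable:
        raise EmptySummaryError(f"FOV {fov_id} has no classifiable track")
    counts = {cls: 0 for cls in BEHAVIOR_ORDER}
    for tr in usable:
        counts[classify_behavior(compute_metrics(tr), thresholds)] += 1
    n = len(usable)
    freqs = {cls: counts[cls] / n for cls in BEHAVIOR_ORDER}
    return FovBehaviorSummary(
        fov_id=fov_id,
        counts=counts,
        frequencies=freqs,
        n_tracks=n,
        n_excluded_single_point=len(dropped),
    )


def summarize_by_fov(
    tracks: Sequence[Track],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> pd.DataFrame:
    """One summary row per FOV: counts and frequencies of each class."""
    rows = []
    by_fov: dict[str, list[Track]] = {}
    for tr in tracks:
        by_fov.setdefault(tr.fov_id, []).append(tr)
    for fov_id in sorted(by_fov):
        try:
            s = summarize_fov(by_fov[fov_id], thresholds)
        except EmptySummaryError:
            continue
        row: dict[str, object] = {"fov_id": fov_id, "n_tracks": s.n_tracks}
        for cls in BEHAVIOR_ORDER:
            row[f"count_{cls.value}"] = s.counts[cls]
        for cls in BEHAVIOR_ORDER:
            row[f"freq_{cls.value}"] = s.frequencies[cls]
        rows.append(row)
    return pd.DataFrame(rows)


def write_classification(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)
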