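"""Seeded generator of synthetic intravital movies.

Tracks are drawn from a correlated (persistent) random walk per motility
mode: step lengths follow a gamma distribution with configured mean speed
and spread, headings evolve by wrapped-normal turning with a persistence
parameter (0 = uniform re-orientation, 1 = straight line), and each mode's
track lifetime is drawn from its duration range.  Arrested modes (adherent,
crawling) reflect at the field-of-view borders; transiting modes
(patrolling, tethering) terminate on border contact once past their minimum
lifetime, emulating exit from the field of view.

The default presets generate the four behavior classes well separated from
the classifier thresholds so that end-to-end label recovery can be measured
against generation truth.  Three scenario presets mimic a control arm, an
exposure arm with heavy neutrophil recruitment, and a sensory-neuron-ablated
arm with fewer but more motile cells.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .behavior import BehaviorClass
from .tracks import Movie, Track, TrackPoint

_TRANSIT_MODES = {BehaviorClass.PATROLLING, BehaviorClass.TETHERING}


@dataclass(frozen=True)
class MotilityModeParams:
    """Random-walk parameters of one motility mode."""

    mode: BehaviorClass
    speed_um_per_s: float
    speed_sd: float
    persistence: float
    duration_range_s: tuple[float, float]
    entry: str = "interior"  # or "boundary"

    def __post_init__(self) -> None:
        if self.speed_um_per_s < 0 or self.speed_sd < 0:
            raise ValueError("speed and spread must be non-negative")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must lie in [0, 1]")
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError("duration range must satisfy 0 < min <= max")
        if self.entry not in ("interior", "boundary"):
            raise ValueError("entry must be 'interior' or 'boundary'")


@dataclass(frozen=True)
class MovieScenario:
    """One synthetic movie: FOV geometry, duration, per-mode track counts."""

    label: str
    duration_s: float
    width_um: float
    height_um: float
    counts: Mapping[BehaviorClass, int]
    mode_params: Mapping[BehaviorClass, MotilityModeParams]
    frame_interval_s: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.frame_interval_s <= 0:
            raise ValueError("movie duration and frame interval must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("track counts must be non-negative")
        for mode, n in self.counts.items():
            if n > 0 and mode not in self.mode_params:
                raise ValueError(f"no motility parameters for mode {mode}")
            if n > 0 and self.mode_params[mode].duration_range_s[1] > self.duration_s:
                raise ValueError(
                    f"{mode.value} duration range exceeds the movie duration"
                )

    @property
    def fov_id(self) -> str:
        return re.sub(r"[^A-Za-z0-9_.-]+", "_", self.label)


def default_mode_params() -> dict[BehaviorClass, MotilityModeParams]:
    """Well-separated presets for the four modes (20-min movie scale)."""
    return {
        BehaviorClass.ADHERENT: MotilityModeParams(
            mode=BehaviorClass.ADHERENT,
            speed_um_per_s=0.005,
            speed_sd=0.002,
            persistence=0.0,
            duration_range_s=(1000.0, 1200.0),
        ),
        BehaviorClass.CRAWLING: MotilityModeParams(
            mode=BehaviorClass.CRAWLING,
            speed_um_per_s=0.12,
            speed_sd=0.03,
            persistence=0.7,
            duration_range_s=(700.0, 1100.0),
        ),
        BehaviorClass.PATROLLING: MotilityModeParams(
            mode=BehaviorClass.PATROLLING,
            speed_um_per_s=0.15,
            speed_sd=0.04,
            persistence=0.8,
            duration_range_s=(200.0, 500.0),
            entry="boundary",
        ),
        BehaviorClass.TETHERING: MotilityModeParams(
            mode=BehaviorClass.TETHERING,
            speed_um_per_s=0.2,
            speed_sd=0.05,
            persistence=0.6,
            duration_range_s=(60.0, 120.0),
            entry="boundary",
        ),
    }


def neutrophil_scenario(
    label: str = "synthetic_fov",
    counts: Mapping[BehaviorClass, int] | None = None,
    seed: int = 0,
    **overrides,
) -> MovieScenario:
    """A 20-minute movie with the default mode presets."""
    if counts is None:
        counts = {mode: 10 for mode in BehaviorClass}
    kwargs = dict(
        label=label,
        duration_s=1200.0,
        width_um=400.0,
        height_um=400.0,
        counts=dict(counts),
        mode_params=default_mode_params(),
        frame_interval_s=10.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return MovieScenario(**kwargs)


def _mode_rng(seed: int, mode_index: int, track_index: int) -> np.random.Generator:
    # independent substream per track: adding tracks never perturbs earlier ones
    ss = np.random.SeedSequence(seed, spawn_key=(mode_index, track_index))
    return np.random.default_rng(ss)


def _step_lengths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    if mean <= 0:
        return np.zeros(n)
    if sd <= 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


def _turns(rng: np.random.Generator, n: int, persistence: float) -> np.ndarray:
    if persistence == 0.0:
        return rng.uniform(-np.pi, np.pi, size=n)
    sigma = np.pi * (1.0 - persistence)
    raw = rng.normal(0.0, sigma, size=n)
    return np.mod(raw + np.pi, 2 * np.pi) - np.pi


def _reflect(v: float, hi: float) -> float:
    period = 2 * hi
    v = v % period
    return period - v if v > hi else v


def simulate_track(
    params: MotilityModeParams,
    scenario: MovieScenario,
    rng: np.random.Generator,
    track_id: str,
) -> Track:
    """Simulate one correlated-random-walk track inside the scenario's FOV."""
    dt = scenario.frame_interval_s
    lo, hi = params.duration_range_s
    lifetime = rng.uniform(lo, hi)
    n_steps = max(1, int(lifetime // dt))
    latest_start = scenario.duration_s - n_steps * dt
    t0 = rng.uniform(0.0, latest_start) if latest_start > 0 else 0.0

    W, H = scenario.width_um, scenario.height_um
    if params.entry == "boundary":
        edge = rng.integers(4)
        u = rng.uniform()
        x, y = [(u * W, 0.0), (u * W, H), (0.0, u * H), (W, u * H)][edge]
    else:
        x, y = rng.uniform(0, W), rng.uniform(0, H)

    heading = rng.uniform(-np.pi, np.pi)
    steps = _step_lengths(rng, n_steps, params.speed_um_per_s * dt, params.speed_sd * dt)
    turns = _turns(rng, n_steps, params.persistence)

    pts = [TrackPoint(t=t0, x=x, y=y)]
    min_steps = max(1, int(lo // dt))
    for k in range(n_steps):
        heading += turns[k]
        nx = x + steps[k] * np.cos(heading)
        ny = y + steps[k] * np.sin(heading)
        exits = not (0 <= nx <= W and 0 <= ny <= H)
        if exits and params.mode in _TRANSIT_MODES and k + 1 >= min_steps:
            # clip the exiting point to the border and terminate (FOV exit)
            x, y = min(max(nx, 0.0), W), min(max(ny, 0.0), H)
            pts.append(TrackPoint(t=t0 + (k + 1) * dt, x=x, y=y))
            break
        if exits:
            nx, ny = _reflect(nx, W), _reflect(ny, H)
        x, y = nx, ny
        pts.append(TrackPoint(t=t0 + (k + 1) * dt, x=x, y=y))
    return Track(fov_id=scenario.fov_id, track_id=track_id, points=tuple(pts))


def simulate_movie(scenario: MovieScenario) -> tuple[Movie, pd.DataFrame]:
    """Generate all tracks of a scenario plus the ground-truth label table.

    Returns the :class:`~motiflux.tracks.Movie` and a table with columns
    ``fov_id, track_id, true_mode``.
    """
    tracks: list[Track] = []
    labels = []
    modes = sorted(scenario.counts, key=lambda m: m.value)
    for mode_index, mode in enumerate(modes):
        n = scenario.counts[mode]
        params = scenario.mode_params[mode] if n > 0 else None
        for i in range(n):
            rng = _mode_rng(scenario.seed, mode_index, i)
            tid = f"{mode.value}_{i:03d}"
            tracks.append(simulate_track(params, scenario, rng, tid))
            labels.append((scenario.fov_id, tid, mode.value))
    movie = Movie(
        fov_id=scenario.fov_id,
        duration_s=scenario.duration_s,
        width_um=scenario.width_um,
        height_um=scenario.height_um,
        tracks=tracks,
    )
    truth = pd.DataFrame(labels, columns=["fov_id", "track_id", "true_mode"])
    return movie, truth


# ---------------------------------------------------------------------------
# Study-arm presets and config I/O
# ---------------------------------------------------------------------------

def study_arm_scenarios(seed: int = 0) -> list[MovieScenario]:
    """Three-arm synthetic experiment: control, exposure, ablated.

    The exposure-like arm recruits many neutrophils that are mostly arrested
    (adherent/tethering); the ablated-like arm has fewer tracks but more
    motile ones, hence a higher median total displacement.  The orderings are
    properties of the configured scenarios, used to exercise the report
    stage, not biological claims.
    """
    base = default_mode_params()
    fast = {
        mode: replace(p, speed_um_per_s=p.speed_um_per_s * 2, speed_sd=p.speed_sd * 2)
        if mode in (BehaviorClass.CRAWLING, BehaviorClass.PATROLLING)
        else p
        for mode, p in base.items()
    }
    return [
        neutrophil_scenario(
            label="control",
            counts={
                BehaviorClass.ADHERENT: 2,
                BehaviorClass.CRAWLING: 3,
                BehaviorClass.PATROLLING: 4,
                BehaviorClass.TETHERING: 1,
            },
            seed=seed,
        ),
        neutrophil_scenario(
            label="exposure",
            counts={
                BehaviorClass.ADHERENT: 18,
                BehaviorClass.CRAWLING: 6,
                BehaviorClass.PATROLLING: 6,
                BehaviorClass.TETHERING: 10,
            },
            seed=seed + 1,
        ),
        neutrophil_scenario(
            label="ablated",
            counts={
                BehaviorClass.ADHERENT: 3,
                BehaviorClass.CRAWLING: 8,
                BehaviorClass.PATROLLING: 8,
                BehaviorClass.TETHERING: 1,
            },
            mode_params=fast,
            seed=seed + 2,
        ),
    ]


def scenario_from_yaml(path: str | Path, seed: int | None = None) -> MovieScenario:
    """Load a MovieScenario from a YAML config.

    Mode parameter entries override the defaults; omitted modes use the
    built-in presets.  An explicit ``seed`` argument overrides the file.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    params = default_mode_params()
    for name, entry in (cfg.get("mode_params") or {}).items():
        mode = BehaviorClass(name)
        entry = dict(entry)
        if "duration_range_s" in entry:
            entry["duration_range_s"] = tuple(entry["duration_range_s"])
        params[mode] = replace(params[mode], **entry)
    counts = {BehaviorClass(k): int(v) for k, v in cfg.get("counts", {}).items()}
    return MovieScenario(
        label=cfg.get("label", "scenario"),
        duration_s=float(cfg.get("duration_s", 1200.0)),
        width_um=float(cfg.get("width_um", 400.0)),
        height_um=float(cfg.get("height_um", 400.0)),
        counts=counts,
        mode_params=params,
        frame_interval_s=float(cfg.get("frame_interval_s", 10.0)),
        seed=int(seed if seed is not None else cfg.get("seed", 0)),
    )
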