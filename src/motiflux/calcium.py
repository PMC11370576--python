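"""Ratiometric (Fura-2) calcium trace scoring.

Traces are F340/F380 ratio series sampled every 3–4 s from cultured vagal
sensory neurons, grouped by dish and experimental batch.  The analysis
chain mirrors common practice for sequential-agonist protocols:

1. **compression** — the trace is reduced to one maximum per 15-s bin,
   and all subsequent scoring runs on the compressed trace (a raw-trace
   flag is available);
2. **amplitude** — for each stimulus window, peak ratio in the window
   (plus a short pad for washout lag) divided by the mean ratio over the
   30 s preceding stimulation;
3. **responder calling** — amplitude at or above a threshold (default 1.2,
   i.e. a 20% rise over baseline); cells enter denominators only if they
   respond to the terminal KCl depolarization (viability gate);
4. **aggregation** — per-dish averages over responders, per-dish responder
   fractions, and batch-wise normalization of fractions to the vehicle
   dishes.

For an ascending concentration series of one agonist delivered
back-to-back (windows sharing edges), every window is scored against the
single pre-series baseline, since later windows have no clean local
baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRACE_TABLE_COLUMNS = ["batch_id", "dish_id", "cell_id", "condition", "t_s", "ratio"]

DEFAULT_RESPONDER_THRESHOLD = 1.2
KCL_NAME = "KCl"


class CoverageError(ValueError):
    """Trace does not cover the baseline or peak-search interval."""


class NoVehicleError(ValueError):
    """Batch has no usable vehicle dishes to normalize against."""


@dataclass(frozen=True)
class CalciumTrace:
    """F340/F380 ratio series of one neuron.

    ``times`` and ``ratios`` are parallel arrays; timestamps strictly
    increase and ratios are positive and finite.
    """

    batch_id: str
    dish_id: str
    cell_id: str
    condition: str
    times: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "ratios", r)
        if t.ndim != 1 or t.shape != r.shape or t.size == 0:
            raise ValueError("times and ratios must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"trace {self.key}: timestamps not strictly increasing")
        if not np.all(np.isfinite(r)) or np.any(r <= 0):
            raise ValueError(f"trace {self.key}: ratios must be positive and finite")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.batch_id, self.dish_id, self.cell_id)

    @property
    def span_s(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class StimulusWindow:
    """One agonist application: name, concentration label, window in seconds."""

    name: str
    concentration_label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(f"window {self.name}: need 0 <= start < end")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.concentration_label}" if self.concentration_label else self.name


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered, non-overlapping stimulus windows plus scoring settings."""

    windows: tuple[StimulusWindow, ...]
    baseline_window_s: float = 30.0
    peak_search_pad_s: float = 30.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "windows", tuple(self.windows))
        if self.baseline_window_s <= 0:
            raise ValueError("baseline window must be positive")
        if self.peak_search_pad_s < 0:
            raise ValueError("peak-search pad must be non-negative")
        for a, b in zip(self.windows, self.windows[1:]):
            if b.start_s < a.end_s:
                raise ValueError(f"windows {a.label} and {b.label} overlap or are unordered")

    def kcl_window(self) -> StimulusWindow | None:
        for w in self.windows:
            if w.name.lower() == KCL_NAME.lower():
                return w
        return None

    def baseline_start(self, stim: StimulusWindow) -> float:
        """Anchor of the pre-stimulus baseline for `stim`.

        Windows of the same agonist delivered back-to-back (an ascending
        concentration series) share the baseline preceding the *first*
        window of the series.
        """
        anchor = stim
        idx = self.windows.index(stim)
        for prev in reversed(self.windows[:idx]):
            if prev.name == anchor.name and prev.end_s == anchor.start_s:
                anchor = prev
            else:
                break
        return anchor.start_s

    def peak_search_end(self, stim: StimulusWindow) -> float:
        """Window end plus the pad, capped at the next stimulus onset."""
        end = stim.end_s + self.peak_search_pad_s
        for w in self.windows:
            if w.start_s >= stim.end_s and w is not stim:
                end = min(end, w.start_s)
                break
        return max(end, stim.end_s)


@dataclass(frozen=True)
class ResponseScore:
    """Amplitude of one cell's response to one stimulus."""

    stimulus: str
    baseline_ratio: float
    peak_ratio: float
    amplitude: float
    responder: bool

    def __post_init__(self) -> None:
        if self.baseline_ratio <= 0:
            raise ValueError("baseline ratio must be positive")
        if not math.isclose(self.amplitude, self.peak_ratio / self.baseline_ratio, rel_tol=1e-12):
            raise ValueError("amplitude must equal peak/baseline")


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def compress_max(trace: CalciumTrace, bin_s: float = 15.0) -> CalciumTrace:
    """Compress a trace to one maximum per half-open bin [k*bin, (k+1)*bin).

    The compressed sample keeps the bin-start timestamp; empty bins are
    omitted.  Applying the same compression twice is the identity.
    """
    if bin_s <= 0:
        raise ValueError("bin size must be positive")
    bins = np.floor(trace.times / bin_s).astype(int)
    uniq, inv = np.unique(bins, return_inverse=True)
    maxima = np.full(uniq.size, -np.inf)
    np.maximum.at(maxima, inv, trace.ratios)
    return CalciumTrace(
        batch_id=trace.batch_id,
        dish_id=trace.dish_id,
        cell_id=trace.cell_id,
        condition=trace.condition,
        times=uniq * bin_s,
        ratios=maxima,
    )


def response_amplitude(
    trace: CalciumTrace,
    stim: StimulusWindow,
    protocol: StimulationProtocol,
) -> tuple[float, float, float]:
    """Baseline, peak and amplitude of one stimulus response.

    baseline = mean ratio over the ``baseline_window_s`` seconds before the
    (series-anchored) stimulation start; peak = max ratio over
    [window start, window end + pad]; amplitude = peak / baseline.
    Raises :class:`CoverageError` when the trace does not span both
    intervals.
    """
    b_anchor = protocol.baseline_start(stim)
    b_lo = b_anchor - protocol.baseline_window_s
    if b_lo < 0:
        raise CoverageError(
            f"stimulus {stim.label}: baseline window starts before t=0 ({b_lo:.1f}s)"
        )
    t = trace.times
    if t[0] > b_lo or t[-1] < stim.end_s:
        raise CoverageError(
            f"trace {trace.key} covers [{t[0]:.1f}, {t[-1]:.1f}]s; stimulus "
            f"{stim.label} needs [{b_lo:.1f}, {stim.end_s:.1f}]s"
        )
    base_mask = (t >= b_lo) & (t < b_anchor)
    if not base_mask.any():
        raise CoverageError(f"stimulus {stim.label}: no samples in baseline window")
    p_hi = protocol.peak_search_end(stim)
    peak_mask = (t >= stim.start_s) & (t <= p_hi)
    if not peak_mask.any():
        raise CoverageError(f"stimulus {stim.label}: no samples in peak-search window")
    baseline = float(trace.ratios[base_mask].mean())
    peak = float(trace.ratios[peak_mask].max())
    return baseline, peak, peak / baseline


def score_cell(
    trace: CalciumTrace,
    protocol: StimulationProtocol,
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
    compress: bool = True,
    bin_s: float = 15.0,
) -> dict[str, ResponseScore]:
    """Score one cell against every window of the protocol.

    By default scoring runs on the 15-s max-compressed trace.
    """
    work = compress_max(trace, bin_s) if compress else trace
    scores: dict[str, ResponseScore] = {}
    for w in protocol.windows:
        baseline, peak, amp = response_amplitude(work, w, protocol)
        scores[w.label] = ResponseScore(
            stimulus=w.label,
            baseline_ratio=baseline,
            peak_ratio=peak,
            amplitude=amp,
            responder=amp >= threshold,
        )
    return scores


def call_responders(
    scores: Mapping[str, ResponseScore],
    protocol: StimulationProtocol,
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
    gate_on_kcl: bool = True,
) -> tuple[dict[str, bool], bool]:
    """Per-stimulus responder booleans plus the cell's inclusion flag.

    A cell is included in denominators only if it responds to KCl (a
    depolarization viability gate).  Requires a KCl window when gating.
    """
    calls = {label: s.amplitude >= threshold for label, s in scores.items()}
    if not gate_on_kcl:
        return calls, True
    kcl = protocol.kcl_window()
    if kcl is None:
        raise ValueError("protocol has no KCl window; cannot apply viability gate")
    if kcl.label not in scores:
        raise ValueError(f"scores lack the KCl window {kcl.label}")
    return calls, calls[kcl.label]


def per_dish_average(scores: Sequence[ResponseScore]) -> float | None:
    """Mean amplitude over responders in one dish for one stimulus.

    Returns ``None`` (dish excluded, logged) when the dish has no responder.
    """
    amps = [s.amplitude for s in scores if s.responder]
    if not amps:
        logger.warning("dish has no responsive neuron for this stimulus; excluded")
        return None
    return float(np.mean(amps))


def normalize_to_vehicle(
    fractions: pd.DataFrame,
    vehicle_label: str = "vehicle",
) -> pd.DataFrame:
    """Normalize per-dish responder fractions to each batch's vehicle mean.

    `fractions` needs columns ``batch_id, dish_id, condition, fraction``.
    Adds ``normalized_fraction`` = fraction / mean(vehicle fractions of the
    same batch).  Raises :class:`NoVehicleError` if a batch lacks vehicle
    dishes or their mean fraction is zero.
    """
    required = {"batch_id", "dish_id", "condition", "fraction"}
    if not required.issubset(fractions.columns):
        raise ValueError(f"fractions table needs columns {sorted(required)}")
    out = fractions.copy()
    out["normalized_fraction"] = np.nan
    for batch, grp in fractions.groupby("batch_id"):
        veh = grp.loc[grp["condition"] == vehicle_label, "fraction"]
        if veh.empty:
            raise NoVehicleError(f"batch {batch}: no {vehicle_label!r} dish")
        veh_mean = veh.mean()
        if veh_mean == 0:
            raise NoVehicleError(f"batch {batch}: vehicle mean fraction is zero")
        out.loc[grp.index, "normalized_fraction"] = grp["fraction"] / veh_mean
    return out


# ---------------------------------------------------------------------------
# Table-level pipeline
# ---------------------------------------------------------------------------

def score_table(
    traces: Sequence[CalciumTrace],
    protocol: StimulationProtocol,
    threshold: float = DEFAULT_RESPONDER_THRESHOLD,
    compress: bool = True,
    gate_on_kcl: bool = True,
) -> pd.DataFrame:
    """Score every cell; one row per (cell, stimulus).

    Columns: ``batch_id, dish_id, cell_id, condition, stimulus,
    baseline_ratio, peak_ratio, amplitude, responder, included``.
    """
    rows = []
    for tr in traces:
        scores = score_cell(tr, protocol, threshold=threshold, compress=compress)
        _, included = call_responders(scores, protocol, threshold, gate_on_kcl=gate_on_kcl)
        for label, s in scores.items():
            rows.append(
                (*tr.key, tr.condition, label, s.baseline_ratio, s.peak_ratio,
                 s.amplitude, s.responder, included)
            )
    return pd.DataFrame(
        rows,
        columns=["batch_id", "dish_id", "cell_id", "condition", "stimulus",
                 "baseline_ratio", "peak_ratio", "amplitude", "responder", "included"],
    )


def dish_responder_fractions(scored: pd.DataFrame, stimulus: str) -> pd.DataFrame:
    """Per-dish fraction of `stimulus` responders among KCl-included cells."""
    sub = scored[(scored["stimulus"] == stimulus) & scored["included"]]
    rows = []
    for (batch, dish, cond), grp in sub.groupby(["batch_id", "dish_id", "condition"]):
        rows.append((batch, dish, cond, len(grp), float(grp["responder"].mean())))
    return pd.DataFrame(
        rows, columns=["batch_id", "dish_id", "condition", "n_cells", "fraction"]
    )


def dish_amplitude_averages(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-dish mean amplitude over responders, per stimulus.

    Dishes with no responder for a stimulus are excluded (logged).
    """
    rows = []
    for (batch, dish, cond, stim), grp in scored.groupby(
        ["batch_id", "dish_id", "condition", "stimulus"]
    ):
        resp = grp[grp["responder"]]
        if resp.empty:
            logger.warning("dish %s/%s has no %s responder; excluded", batch, dish, stim)
            continue
        rows.append((batch, dish, cond, stim, len(resp), float(resp["amplitude"].mean())))
    return pd.DataFrame(
        rows,
        columns=["batch_id", "dish_id", "condition", "stimulus", "n_responders",
                 "mean_amplitude"],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def traces_to_frame(traces: Iterable[CalciumTrace]) -> pd.DataFrame:
    rows = [
        (tr.batch_id, tr.dish_id, tr.cell_id, tr.condition, t, r)
        for tr in traces
        for t, r in zip(tr.times, tr.ratios)
    ]
    return pd.DataFrame(rows, columns=TRACE_TABLE_COLUMNS)


def frame_to_traces(df: pd.DataFrame) -> list[CalciumTrace]:
    missing = [c for c in TRACE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace table missing columns: {missing}")
    traces = []
    for (batch, dish, cell, cond), grp in df.groupby(
        ["batch_id", "dish_id", "cell_id", "condition"], sort=True
    ):
        grp = grp.sort_values("t_s")
        traces.append(
            CalciumTrace(
                batch_id=str(batch),
                dish_id=str(dish),
                cell_id=str(cell),
                condition=str(cond),
                times=grp["t_s"].to_numpy(dtype=float),
                ratios=grp["ratio"].to_numpy(dtype=float),
            )
        )
    return traces


def read_trace_table(path: str | Path, sep: str = ",") -> list[CalciumTrace]:
    """Read a delimited trace table with header
    ``batch_id,dish_id,cell_id,condition,t_s,ratio``."""
    return frame_to_traces(pd.read_csv(path, sep=sep))


def write_trace_table(traces: Sequence[CalciumTrace], path: str | Path, sep: str = ",") -> None:
    traces_to_frame(traces).to_csv(path, sep=sep, index=False)


def protocol_from_yaml(path: str | Path) -> StimulationProtocol:
    """Load a stimulation protocol config.

    YAML schema::

        baseline_window_s: 30
        peak_search_pad_s: 30
        windows:
          - {name: AITC, concentration: 10uM, start_s: 60, end_s: 90}
          - {name: KCl, concentration: 40mM, start_s: 420, end_s: 435}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    windows = tuple(
        StimulusWindow(
            name=str(w["name"]),
            concentration_label=str(w.get("concentration", "")),
            start_s=float(w["start_s"]),
            end_s=float(w["end_s"]),
        )
        for w in cfg["windows"]
    )
    return StimulationProtocol(
        windows=windows,
        baseline_window_s=float(cfg.get("baseline_window_s", 30.0)),
        peak_search_pad_s=float(cfg.get("peak_search_pad_s", 30.0)),
    )


def ascending_aitc_protocol() -> StimulationProtocol:
    """Sequential TRPA1 challenge: ascending AITC series then KCl.

    AITC 10 μM at 60–90 s, 30 μM at 90–120 s, 100 μM at 120–150 s;
    KCl 40 mM at 420–435 s.
    """
    return StimulationProtocol(
        windows=(
            StimulusWindow("AITC", "10uM", 60, 90),
            StimulusWindow("AITC", "30uM", 90, 120),
            StimulusWindow("AITC", "100uM", 120, 150),
            StimulusWindow("KCl", "40mM", 420, 435),
        )
    )


def artemin_sensitization_protocol() -> StimulationProtocol:
    """TRPA1/TRPV1 challenge used for neurotrophic-factor sensitization:
    AITC 300 μM at 240–270 s, capsaicin 300 nM at 320–335 s,
    KCl 40 mM at 720–735 s."""
    return StimulationProtocol(
        windows=(
            StimulusWindow("AITC", "300uM", 240, 270),
            StimulusWindow("capsaicin", "300nM", 320, 335),
            StimulusWindow("KCl", "40mM", 720, 735),
        )
    )
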