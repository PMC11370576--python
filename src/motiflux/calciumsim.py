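"""Seeded generator of synthetic Fura-2 ratio traces with known truth.

Each simulated neuron has a flat baseline ratio plus Gaussian noise.  For
every stimulus it truly responds to, a transient is added: a linear rise
across the stimulus window up to ``baseline * (amplitude - 1)`` above
baseline, then exponential decay with time constant ``decay_tau_s``.  KCl
responsiveness (the viability gate) is drawn independently at a high rate.
The generator records per-cell, per-stimulus truth labels so that scoring
pipelines can be validated against generation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calcium import (
    CalciumTrace,
    StimulationProtocol,
    StimulusWindow,
)


def single_challenge_protocol() -> StimulationProtocol:
    """One TRPA1 challenge plus a terminal KCl depolarization.

    AITC 300 μM at 240–270 s; KCl 40 mM at 420–435 s.  The windows are far
    apart so each has a clean local baseline — the preferred layout for
    responder-recovery validation.
    """
    return StimulationProtocol(
        windows=(
            StimulusWindow("AITC", "300uM", 240, 270),
            StimulusWindow("KCl", "40mM", 420, 435),
        )
    )


@dataclass(frozen=True)
class TraceScenario:
    """Configuration of one synthetic calcium-imaging experiment.

    ``responder_fraction`` maps a stimulus window label (or a stimulus name,
    applying to every window of that name) to the true responder
    probability; per-condition overrides take precedence.  KCl is governed
    by ``kcl_responder_rate`` instead.
    """

    protocol: StimulationProtocol = field(default_factory=single_challenge_protocol)
    conditions: tuple[str, ...] = ("vehicle", "treated")
    n_dishes: int = 4
    cells_per_dish: int = 25
    n_batches: int = 1
    responder_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"AITC": 0.3}
    )
    condition_overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    true_amplitude: float = 1.5
    kcl_amplitude: float = 2.0
    kcl_responder_rate: float = 0.95
    decay_tau_s: float = 20.0
    baseline_level: float = 0.8
    noise_sd: float = 0.03
    sample_interval_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = list(self.responder_fraction.values()) + [
            f for ov in self.condition_overrides.values() for f in ov.values()
        ]
        if any(not (0 <= f <= 1) for f in fracs + [self.kcl_responder_rate]):
            raise ValueError("responder fractions must lie in [0, 1]")
        if self.true_amplitude < 1 or self.kcl_amplitude < 1:
            raise ValueError("amplitudes are peak/baseline factors and must be >= 1")
        if self.noise_sd < 0 or self.baseline_level <= 0:
            raise ValueError("baseline must be positive and noise non-negative")
        if self.sample_interval_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("sample interval and decay tau must be positive")

    @property
    def span_s(self) -> float:
        return self.protocol.windows[-1].end_s + self.protocol.peak_search_pad_s

    def fraction_for(self, window: StimulusWindow, condition: str) -> float:
        """True responder probability for one window under one condition."""
        if window.name.lower() == "kcl":
            return self.kcl_responder_rate
        for table in (self.condition_overrides.get(condition, {}), self.responder_fraction):
            if window.label in table:
                return table[window.label]
            if window.name in table:
                return table[window.name]
        return 0.0


def _cell_rng(scenario: TraceScenario, key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(scenario.seed, spawn_key=key))


def simulate_trace(
    scenario: TraceScenario,
    responds_to: Mapping[str, bool],
    rng: np.random.Generator,
    batch_id: str = "b0",
    dish_id: str = "d0",
    cell_id: str = "c0",
    condition: str = "vehicle",
) -> CalciumTrace:
    """Simulate one neuron's ratio trace given its true responder flags.

    ``responds_to`` maps window labels to truth; a true response adds a
    transient rising linearly across the window to the configured amplitude
    and decaying exponentially afterwards.
    """
    dt = scenario.sample_interval_s
    t = np.arange(0.0, scenario.span_s + dt / 2, dt)
    base = scenario.baseline_level
    r = np.full_like(t, base)
    for w in scenario.protocol.windows:
        if not responds_to.get(w.label, False):
            continue
        amp = scenario.kcl_amplitude if w.name.lower() == "kcl" else scenario.true_amplitude
        delta = base * (amp - 1.0)
        rise = (t >= w.start_s) & (t <= w.end_s)
        r[rise] += delta * (t[rise] - w.start_s) / (w.end_s - w.start_s)
        decay = t > w.end_s
        r[decay] += delta * np.exp(-(t[decay] - w.end_s) / scenario.decay_tau_s)
    if scenario.noise_sd > 0:
        r = r + rng.normal(0.0, scenario.noise_sd, size=t.size)
    r = np.maximum(r, 1e-6)  # ratios must stay positive
    return CalciumTrace(
        batch_id=batch_id,
        dish_id=dish_id,
        cell_id=cell_id,
        condition=condition,
        times=t,
        ratios=r,
    )


def simulate_batch(scenario: TraceScenario) -> tuple[list[CalciumTrace], pd.DataFrame]:
    """Generate every dish and condition of the scenario.

    Returns the traces and a truth table with one row per (cell, stimulus):
    ``batch_id, dish_id, cell_id, condition, stimulus, true_responder``.
    """
    traces: list[CalciumTrace] = []
    truth_rows = []
    for bi in range(scenario.n_batches):
        batch_id = f"b{bi}"
        for ci, condition in enumerate(scenario.conditions):
            for di in range(scenario.n_dishes):
                dish_id = f"{condition}_d{di}"
                for cell in range(scenario.cells_per_dish):
                    rng = _cell_rng(scenario, (bi, ci, di, cell))
                    cell_id = f"c{cell}"
                    responds = {
                        w.label: bool(rng.uniform() < scenario.fraction_for(w, condition))
                        for w in scenario.protocol.windows
                    }
                    traces.append(
                        simulate_trace(
                            scenario,
                            responds,
                            rng,
                            batch_id=batch_id,
                            dish_id=dish_id,
                            cell_id=cell_id,
                            condition=condition,
                        )
                    )
                    for w in scenario.protocol.windows:
                        truth_rows.append(
                            (batch_id, dish_id, cell_id, condition, w.label,
                             responds[w.label])
                        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["batch_id", "dish_id", "cell_id", "condition", "stimulus",
                 "true_responder"],
    )
    return traces, truth
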