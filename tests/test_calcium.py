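"""Calcium trace scoring: compression, amplitudes, responder calling,
per-dish aggregation and vehicle normalization."""

import numpy as np
import pandas as pd
import pytest

from motiflux import (
    CalciumTrace,
    CoverageError,
    NoVehicleError,
    ResponseScore,
    StimulationProtocol,
    StimulusWindow,
    ascending_aitc_protocol,
    artemin_sensitization_protocol,
    call_responders,
    compress_max,
    normalize_to_vehicle,
    per_dish_average,
    response_amplitude,
    score_cell,
    score_table,
)
from motiflux.calcium import (
    dish_responder_fractions,
    frame_to_traces,
    protocol_from_yaml,
    read_trace_table,
    traces_to_frame,
    write_trace_table,
)


def trace(times, ratios, **ids):
    kw = dict(batch_id="b0", dish_id="d0", cell_id="c0", condition="vehicle")
    kw.update(ids)
    return CalciumTrace(times=np.asarray(times, float),
                        ratios=np.asarray(ratios, float), **kw)


def flat_trace(level=1.0, span=500.0, dt=3.0, **ids):
    t = np.arange(0.0, span + dt / 2, dt)
    return trace(t, np.full_like(t, level), **ids)


class TestTraceValidation:
    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            trace([0, 3], [1.0, 0.0])

    def test_non_increasing_time_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            trace([0, 0], [1.0, 1.0])

    def test_window_order_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulationProtocol(windows=(
                StimulusWindow("A", "", 100, 200),
                StimulusWindow("B", "", 150, 250),
            ))


class TestCompressMax:
    def test_bin_maximum(self):
        """Samples every 3 s with ratios 1,2,3,2,1 in the first 15 s give a
        first compressed value of 3."""
        tr = trace([0, 3, 6, 9, 12], [1, 2, 3, 2, 1])
        out = compress_max(tr, 15.0)
        assert out.times[0] == 0.0
        assert out.ratios[0] == 3.0
        assert len(out.times) == 1

    def test_constant_trace_unchanged_values(self):
        tr = flat_trace(level=0.8, span=60)
        out = compress_max(tr, 15.0)
        assert np.all(out.ratios == 0.8)

    def test_half_open_bins_at_4s_sampling(self):
        """Samples at 0,4,8,12,16 s fall into bins [0,15) (4 samples) and
        [15,30) (1 sample)."""
        tr = trace([0, 4, 8, 12, 16], [1, 2, 5, 2, 4])
        out = compress_max(tr, 15.0)
        assert list(out.times) == [0.0, 15.0]
        assert list(out.ratios) == [5.0, 4.0]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 450, 3.0)
        tr = trace(t, 0.8 + 0.1 * rng.random(t.size))
        once = compress_max(tr, 15.0)
        twice = compress_max(once, 15.0)
        assert np.array_equal(once.times, twice.times)
        assert np.array_equal(once.ratios, twice.ratios)

    def test_empty_bins_omitted(self):
        tr = trace([0, 3, 100], [1, 2, 3])
        out = compress_max(tr, 15.0)
        assert list(out.times) == [0.0, 90.0]


class TestResponseAmplitude:
    protocol = StimulationProtocol(windows=(
        StimulusWindow("AITC", "300uM", 240, 270),
        StimulusWindow("KCl", "40mM", 420, 435),
    ))

    def test_peak_over_baseline(self):
        t = np.arange(0.0, 470.0, 3.0)
        r = np.ones_like(t)
        r[(t >= 240) & (t <= 270)] = 1.5
        tr = trace(t, r)
        baseline, peak, amp = response_amplitude(tr, self.protocol.windows[0], self.protocol)
        assert baseline == pytest.approx(1.0)
        assert peak == pytest.approx(1.5)
        assert amp == pytest.approx(1.5)

    def test_flat_trace_amplitude_one(self):
        tr = flat_trace(level=0.7)
        for w in self.protocol.windows:
            _, _, amp = response_amplitude(tr, w, self.protocol)
            assert amp == pytest.approx(1.0)

    def test_scale_invariance(self):
        t = np.arange(0.0, 470.0, 3.0)
        rng = np.random.default_rng(1)
        r = 0.8 + 0.05 * rng.random(t.size)
        for c in (0.1, 10.0):
            _, _, amp0 = response_amplitude(trace(t, r), self.protocol.windows[0], self.protocol)
            _, _, ampc = response_amplitude(trace(t, c * r), self.protocol.windows[0], self.protocol)
            assert ampc == pytest.approx(amp0, rel=1e-12)

    def test_insufficient_coverage(self):
        t = np.arange(220.0, 470.0, 3.0)  # starts after the baseline window opens
        with pytest.raises(CoverageError):
            response_amplitude(trace(t, np.ones_like(t)),
                               self.protocol.windows[0], self.protocol)

    def test_trace_starting_late_for_early_stimulus(self):
        proto = StimulationProtocol(windows=(StimulusWindow("AITC", "", 60, 90),))
        t = np.arange(50.0, 200.0, 3.0)
        with pytest.raises(CoverageError):
            response_amplitude(trace(t, np.ones_like(t)), proto.windows[0], proto)

    def test_ascending_series_shares_pre_series_baseline(self):
        """All three windows of a back-to-back concentration series are
        scored against the baseline before the first window."""
        proto = ascending_aitc_protocol()
        for w in proto.windows[:3]:
            assert proto.baseline_start(w) == 60.0
        assert proto.baseline_start(proto.windows[3]) == 420.0

    def test_peak_search_capped_at_next_onset(self):
        proto = ascending_aitc_protocol()
        assert proto.peak_search_end(proto.windows[0]) == 90.0
        assert proto.peak_search_end(proto.windows[2]) == 180.0
        assert proto.peak_search_end(proto.windows[3]) == 465.0


class TestResponderCalling:
    protocol = TestResponseAmplitude.protocol

    @staticmethod
    def scores(aitc_amp, kcl_amp):
        return {
            "AITC_300uM": ResponseScore("AITC_300uM", 1.0, aitc_amp, aitc_amp,
                                        aitc_amp >= 1.2),
            "KCl_40mM": ResponseScore("KCl_40mM", 1.0, kcl_amp, kcl_amp,
                                      kcl_amp >= 1.2),
        }

    def test_responder_and_included(self):
        calls, included = call_responders(self.scores(1.5, 2.0), self.protocol)
        assert calls["AITC_300uM"] and included

    def test_kcl_failure_excludes_cell(self):
        calls, included = call_responders(self.scores(1.5, 1.05), self.protocol)
        assert calls["AITC_300uM"]
        assert not included

    def test_threshold_is_inclusive(self):
        calls, _ = call_responders(self.scores(1.2, 2.0), self.protocol, threshold=1.2)
        assert calls["AITC_300uM"]

    def test_missing_kcl_window_is_config_error(self):
        proto = StimulationProtocol(windows=(StimulusWindow("AITC", "", 240, 270),))
        scores = {"AITC": ResponseScore("AITC", 1.0, 1.5, 1.5, True)}
        with pytest.raises(ValueError, match="KCl"):
            call_responders(scores, proto)
        calls, included = call_responders(scores, proto, gate_on_kcl=False)
        assert included


class TestAggregation:
    def test_per_dish_average_over_responders_only(self):
        scores = [
            ResponseScore("A", 1.0, 1.2, 1.2, True),
            ResponseScore("A", 1.0, 1.4, 1.4, True),
            ResponseScore("A", 1.0, 1.05, 1.05, False),
        ]
        assert per_dish_average(scores) == pytest.approx(1.3)

    def test_single_responder(self):
        assert per_dish_average([ResponseScore("A", 1.0, 1.7, 1.7, True)]) == 1.7

    def test_no_responder_dish_excluded(self, caplog):
        with caplog.at_level("WARNING"):
            out = per_dish_average([ResponseScore("A", 1.0, 1.0, 1.0, False)])
        assert out is None
        assert "no responsive neuron" in caplog.text

    def test_normalize_to_vehicle(self):
        df = pd.DataFrame({
            "batch_id": ["b0"] * 3 + ["b1"] * 2,
            "dish_id": ["d0", "d1", "d2", "d0", "d1"],
            "condition": ["vehicle", "vehicle", "treated", "vehicle", "treated"],
            "fraction": [0.1, 0.3, 0.3, 0.25, 0.5],
        })
        out = normalize_to_vehicle(df)
        # b0 vehicle mean 0.2 -> treated 1.5; b1 vehicle mean 0.25 -> treated 2.0
        assert out.loc[2, "normalized_fraction"] == pytest.approx(1.5)
        assert out.loc[4, "normalized_fraction"] == pytest.approx(2.0)
        # mean vehicle normalized fraction is 1 per batch by construction
        veh = out[out.condition == "vehicle"]
        assert veh.groupby("batch_id")["normalized_fraction"].mean().tolist() == \
            pytest.approx([1.0, 1.0])

    def test_batch_without_vehicle_errors(self):
        df = pd.DataFrame({"batch_id": ["b0"], "dish_id": ["d0"],
                           "condition": ["treated"], "fraction": [0.3]})
        with pytest.raises(NoVehicleError):
            normalize_to_vehicle(df)


class TestTableLevel:
    def test_score_table_and_fractions(self):
        proto = TestResponseAmplitude.protocol
        t = np.arange(0.0, 470.0, 3.0)
        traces = []
        for i, (aitc, kcl) in enumerate([(1.6, 2.0), (1.0, 2.0), (1.6, 1.0)]):
            r = np.ones_like(t)
            r[(t >= 240) & (t <= 270)] *= aitc
            r[(t >= 420) & (t <= 435)] *= kcl
            traces.append(trace(t, r, cell_id=f"c{i}"))
        scored = score_table(traces, proto)
        assert len(scored) == 6  # 3 cells x 2 windows
        by_cell = scored[scored.stimulus == "AITC_300uM"].set_index("cell_id")
        assert by_cell.loc["c0", "responder"]
        assert not by_cell.loc["c1", "responder"]
        assert by_cell.loc["c0", "included"]
        assert not by_cell.loc["c2", "included"]  # KCl non-responder gated out
        fr = dish_responder_fractions(scored, "AITC_300uM")
        assert fr["n_cells"].item() == 2
        assert fr["fraction"].item() == pytest.approx(0.5)

    def test_trace_io_roundtrip(self, tmp_path):
        tr = flat_trace(level=0.9, span=60, cell_id="c7")
        path = tmp_path / "traces.csv"
        write_trace_table([tr], path)
        (back,) = read_trace_table(path)
        assert back.key == tr.key
        assert np.allclose(back.ratios, tr.ratios)

    def test_protocol_yaml(self, tmp_path):
        cfg = tmp_path / "protocol.yaml"
        cfg.write_text(
            "baseline_window_s: 30\npeak_search_pad_s: 30\nwindows:\n"
            "  - {name: AITC, concentration: 300uM, start_s: 240, end_s: 270}\n"
            "  - {name: KCl, concentration: 40mM, start_s: 420, end_s: 435}\n"
        )
        proto = protocol_from_yaml(cfg)
        assert proto.windows[0].label == "AITC_300uM"
        assert proto.kcl_window().start_s == 420

    def test_builtin_protocols_valid(self):
        assert len(ascending_aitc_protocol().windows) == 4
        assert artemin_sensitization_protocol().kcl_window().end_s == 735
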