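"""Normalization, T25 latency, first-responder ranking, AUC, Fmax, phases."""

import math

import numpy as np
import pandas as pd
import pytest

from isletpulse import (
    DegenerateTraceError,
    NoResponseError,
    ProtocolError,
    StimulusEvent,
    StimulusProtocol,
    TraceMatrix,
    build_response_table,
    compute_auc,
    compute_fmax,
    compute_t25,
    first_responder_from_table,
    identify_first_responder,
    normalize_baseline,
    normalize_minmax,
    phase_peak_metrics,
)
from isletpulse.response import ResponseConfig


class TestNormalizeMinmax:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([2, 4, 6], [0.0, 0.5, 1.0]),
            ([10, 12, 20, 14], [0.0, 0.2, 1.0, 0.4]),
        ],
    )
    def test_hand_arithmetic(self, raw, expected):
        out = normalize_minmax(np.array(raw, dtype=float))
        np.testing.assert_allclose(out.values, expected)

    def test_constant_trace_raises(self):
        with pytest.raises(DegenerateTraceError):
            normalize_minmax(np.array([5.0, 5.0, 5.0]))

    def test_reference_window_rescales_whole_trace(self):
        out = normalize_minmax(np.array([0.0, 10.0, 20.0, 40.0]), window=slice(0, 3))
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0, 2.0])


class TestNormalizeBaseline:
    @pytest.mark.parametrize(
        "raw, expected",
        [([10, 20, 30], [0.0, 1.0, 2.0]), ([8, 10, 12], [0.0, 0.25, 0.5])],
    )
    def test_hand_arithmetic(self, raw, expected):
        out = normalize_baseline(np.array(raw, dtype=float))
        np.testing.assert_allclose(out.values, expected)

    def test_zero_baseline_raises(self):
        with pytest.raises(DegenerateTraceError):
            normalize_baseline(np.array([0.0, 1.0, 2.0]))


class TestT25:
    def test_step_response(self):
        fs, stim = 6.0, 5.0
        t = np.arange(120) / fs
        x = (t >= stim + 2.0).astype(float)
        t25 = compute_t25(x, stim, fs=fs)
        assert abs(t25 - 2.0) <= 1.0 / fs

    def test_plateau_below_threshold_censored(self):
        x = np.full(60, 0.2)
        assert math.isnan(compute_t25(x, 1.0, fs=6.0))

    def test_linear_ramp_matches_frame_scan_oracle(self):
        fs, stim = 6.0, 2.0
        t = np.arange(120) / fs
        x = np.clip((t - stim) / 12.0, 0.0, 1.0)
        # oracle: scan frames after the stimulus for the first value > 0.25
        expected = next(
            t[k] - stim for k in range(len(t)) if t[k] >= stim and x[k] > 0.25
        )
        assert compute_t25(x, stim, fs=fs) == pytest.approx(expected)
        assert expected == pytest.approx(3.1667, abs=1e-3)

    def test_interpolated_crossing_on_ramp(self):
        fs, stim = 6.0, 0.0
        t = np.arange(120) / fs
        x = np.clip(t / 12.0, 0.0, 1.0)
        assert compute_t25(x, stim, fs=fs, interpolate=True) == pytest.approx(3.0)

    def test_stimulus_after_recording_raises(self):
        with pytest.raises(ProtocolError):
            compute_t25(np.zeros(10), 100.0, fs=6.0)

    def test_shift_equivariance(self):
        fs = 6.0
        t = np.arange(300) / fs
        x = np.clip((t - 10.0) / 5.0, 0.0, 1.0)
        base = compute_t25(x, 10.0, fs=fs)
        for shift_frames in (6, 30, 60):
            shifted = np.concatenate([np.zeros(shift_frames), x])[: len(x)]
            assert compute_t25(shifted, 10.0 + shift_frames / fs, fs=fs) == pytest.approx(base)


class TestFirstResponder:
    def test_minimum_mean_wins(self):
        df = pd.DataFrame({0: [4.0, 2.5, 7.1]}, index=["A", "B", "C"])
        assert identify_first_responder(df) == "B"

    def test_tie_breaks_on_first_stimulus_then_id(self):
        df = pd.DataFrame(
            {0: [2.0, 3.0], 1: [4.0, 3.0]}, index=["A", "B"]
        )  # equal means (3.0); A faster at stimulus 0
        assert identify_first_responder(df) == "A"
        df2 = pd.DataFrame({0: [3.0, 3.0], 1: [3.0, 3.0]}, index=["B", "A"])
        assert identify_first_responder(df2) == "A"

    def test_full_responders_precede_partial(self):
        # rank oracle: cells responding to all stimuli strictly precede any
        # partially censored cell, whatever the means say
        df = pd.DataFrame(
            {0: [5.0, 1.0], 1: [5.0, math.nan], 2: [5.0, 1.0]}, index=["A", "B"]
        )
        assert identify_first_responder(df) == "A"

    def test_all_censored_raises(self):
        df = pd.DataFrame({0: [math.nan, math.nan]}, index=["A", "B"])
        with pytest.raises(NoResponseError):
            identify_first_responder(df)


class TestAUC:
    def test_zero_trace_zero_auc(self):
        auc, trunc = compute_auc(np.zeros(400), 1.0, window_frames=250, fs=250 / 37.5)
        assert auc == 0.0 and not trunc

    def test_constant_one_equals_window_duration(self):
        fs = 250 / 37.5
        auc, _ = compute_auc(np.ones(400), 0.0, window_frames=250, fs=fs)
        assert auc == pytest.approx(37.5)

    def test_triangular_pulse_matches_trapezoid_oracle(self):
        fs = 10.0
        t = np.arange(600) / fs
        x = np.interp(t, [10.0, 15.0, 20.0], [0.0, 1.0, 0.0])  # base 10 s, height 1
        auc, _ = compute_auc(x, 5.0, window_frames=250, fs=fs)
        i0 = 50
        oracle = np.trapezoid(x[i0 : i0 + 251], dx=1 / fs)
        assert auc == pytest.approx(oracle)
        assert auc == pytest.approx(5.0, abs=1e-6)

    def test_window_truncation_flagged(self):
        _, trunc = compute_auc(np.ones(100), 5.0, window_frames=250, fs=10.0)
        assert trunc

    def test_linearity_and_additivity(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, size=500)
        fs = 10.0
        a1, _ = compute_auc(x, 0.0, 200, fs=fs)
        a3, _ = compute_auc(3 * x, 0.0, 200, fs=fs)
        assert a3 == pytest.approx(3 * a1)
        left, _ = compute_auc(x, 0.0, 100, fs=fs)
        right, _ = compute_auc(x, 10.0, 100, fs=fs)
        assert left + right == pytest.approx(a1)


class TestFmaxAndPhases:
    def test_fmax_scan(self):
        assert compute_fmax(np.array([0.0, 1.0, 2.0])) == 2.0
        assert compute_fmax(np.zeros(5)) == 0.0
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 3, 100)
        assert compute_fmax(x) == max(float(v) for v in x)

    def test_first_phase_rectangular_pulse(self):
        fs = 10.0
        x = np.zeros(600)
        x[100:200] = 0.8  # 10 s pulse
        m = phase_peak_metrics(x, (0.0, 60.0), "first", fs=fs)
        assert m.amplitude == pytest.approx(0.8)
        assert m.width_s == pytest.approx(10.0)

    def test_second_phase_two_pulses_mean_amplitude(self):
        fs = 10.0
        x = np.zeros(1200)
        x[200:280] = 0.6
        x[600:680] = 1.0
        m = phase_peak_metrics(x, (0.0, 120.0), "second", fs=fs)
        assert m.n_peaks == 2
        assert m.amplitude == pytest.approx(0.8)
        assert m.width_s == pytest.approx(8.0)

    def test_second_phase_no_peaks_flagged(self):
        m = phase_peak_metrics(np.zeros(100), (0.0, 9.9), "second", fs=10.0)
        assert m.empty and m.amplitude == 0.0 and m.width_s == 0.0

    def test_noisy_two_peak_trace_matches_peak_scan_oracle(self):
        rng = np.random.default_rng(9)
        fs = 10.0
        t = np.arange(1200) / fs
        x = (
            0.9 * np.exp(-0.5 * ((t - 30) / 3) ** 2)
            + 0.7 * np.exp(-0.5 * ((t - 80) / 3) ** 2)
            + rng.normal(0, 0.01, t.size)
        )
        m = phase_peak_metrics(x, (0.0, 120.0), "second", fs=fs, peak_min_sep_s=20.0)
        # brute-force scan oracle: one maximum per known peak neighbourhood
        assert m.n_peaks == 2
        tops = [x[250:350].max(), x[750:850].max()]
        assert m.amplitude == pytest.approx(np.mean(tops), rel=1e-6)


class TestResponseTable:
    def test_table_covers_all_cell_stimulus_pairs(self):
        fs = 6.0
        t = np.arange(1800) / fs  # 300 s
        stim_times = (60.0, 180.0)
        cells = {}
        for k, delay in enumerate([1.0, 5.0, 9.0]):
            x = np.zeros_like(t)
            for s in stim_times:
                x += np.where(t >= s + delay, np.exp(-(t - s - delay) / 20.0), 0.0)
            cells[f"c{k}"] = 100.0 * (1.0 + x)
        tm = TraceMatrix(tuple(cells), np.column_stack(list(cells.values())), fs=fs)
        proto = StimulusProtocol(
            events=tuple(StimulusEvent("glucose", s) for s in stim_times),
            baseline_window=(0.0, 60.0),
        )
        table = build_response_table(tm, proto)
        assert len(table) == 6
        assert not table["censored"].any()
        assert first_responder_from_table(table) == "c0"
        # latencies ordered like the injected delays, per stimulus
        for k in (0, 1):
            sub = table[table["stimulus"] == k].set_index("cell_id")["t25_s"]
            assert sub["c0"] < sub["c1"] < sub["c2"]

    def test_empty_protocol_raises(self):
        tm = TraceMatrix(("a", "b"), np.random.default_rng(0).uniform(50, 60, (20, 2)), fs=6.0)
        with pytest.raises(ProtocolError):
            build_response_table(tm, StimulusProtocol(events=()))
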