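"""Per-cell glucose-response statistics from calcium indicator traces.

Two normalizations are used throughout, mirroring common practice for
genetically encoded calcium indicators (GCaMP, K-GECO):

* **min-max**: ``(F_t - F_min) / (F_max - F_min)`` maps a trace onto [0, 1]
  so that onset latencies are comparable across cells and islets regardless
  of absolute brightness;
* **baseline**: ``(F_t - F_min) / F_min`` (a dF/F-style relative change with
  no ceiling) preserves response strength, so a weak or null response is not
  masked by rescaling.

From these the module derives the response-onset latency T25 (time after a
glucose stimulus at which the min-max-normalized trace first exceeds 0.25),
the *first responder* (the cell with the fastest average T25 over repeated
stimulations), the strength of response (trapezoidal AUC of the
baseline-normalized trace over a fixed post-stimulus window), the session
maximum Fmax, and phase-resolved peak amplitude / peak width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (
    DegenerateTraceError,
    NoResponseError,
    ProtocolError,
    ValidationError,
)
from .io import StimulusProtocol, TraceMatrix

__all__ = [
    "NormalizedTrace",
    "ResponseConfig",
    "PhaseMetrics",
    "normalize_minmax",
    "normalize_baseline",
    "compute_t25",
    "identify_first_responder",
    "compute_auc",
    "compute_fmax",
    "phase_peak_metrics",
    "build_response_table",
    "first_responder_from_table",
]

CENSORED = math.nan  # sentinel for "never crossed threshold within the epoch"


@dataclass(frozen=True)
class NormalizedTrace:
    """A normalized single-cell trace with its provenance."""

    values: np.ndarray
    mode: Literal["minmax", "baseline"]
    fs: float
    t0: float = 0.0
    cell_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def _as_values(trace) -> np.ndarray:
    if isinstance(trace, NormalizedTrace):
        return trace.values
    return np.asarray(trace, dtype=float)


def normalize_minmax(
    trace,
    fs: float = 1.0,
    t0: float = 0.0,
    cell_id: str | None = None,
    window: slice | None = None,
) -> NormalizedTrace:
    """Min-max normalize a trace: ``(F - Fmin) / (Fmax - Fmin)``.

    ``window`` selects the frames over which the reference minimum and
    maximum are taken (default: the whole trace); the rescale is applied to
    every frame.  Raises :class:`DegenerateTraceError` on a constant
    reference window.
    """
    x = _as_values(trace)
    if x.size < 2:
        raise ValidationError("need at least 2 frames to normalize")
    ref = x if window is None else x[window]
    fmin, fmax = float(np.min(ref)), float(np.max(ref))
    if fmax <= fmin:
        raise DegenerateTraceError(
            f"constant trace (min == max == {fmin}); cannot min-max normalize"
        )
    return NormalizedTrace((x - fmin) / (fmax - fmin), "minmax", fs, t0, cell_id)


def normalize_baseline(
    trace,
    fs: float = 1.0,
    t0: float = 0.0,
    cell_id: str | None = None,
) -> NormalizedTrace:
    """Baseline-normalize a trace: ``(F - Fmin) / Fmin`` (no ceiling).

    Requires a strictly positive minimum; raises
    :class:`DegenerateTraceError` otherwise.
    """
    x = _as_values(trace)
    fmin = float(np.min(x))
    if fmin <= 0:
        raise DegenerateTraceError(
            f"baseline normalization needs Fmin > 0, got Fmin = {fmin}"
        )
    return NormalizedTrace((x - fmin) / fmin, "baseline", fs, t0, cell_id)


def compute_t25(
    norm_trace,
    stim_time_s: float,
    fs: float | None = None,
    t0: float | None = None,
    epoch_end_s: float | None = None,
    threshold: float = 0.25,
    interpolate: bool = False,
) -> float:
    """Response-onset latency: seconds from stimulus to the first frame whose
    min-max-normalized value strictly exceeds ``threshold``.

    Only frames at or after the stimulus and before ``epoch_end_s`` are
    searched.  Returns NaN (censored) if the threshold is never exceeded in
    the epoch.  With ``interpolate=True`` the crossing time is refined by
    linear interpolation between the bracketing frames.
    """
    if isinstance(norm_trace, NormalizedTrace):
        fs = norm_trace.fs if fs is None else fs
        t0 = norm_trace.t0 if t0 is None else t0
    if fs is None:
        raise ValidationError("fs required when passing a bare array")
    t0 = 0.0 if t0 is None else t0
    x = _as_values(norm_trace)
    times = t0 + np.arange(x.size) / fs
    if stim_time_s > times[-1]:
        raise ProtocolError(
            f"stimulus at {stim_time_s} s lies after the last frame ({times[-1]} s)"
        )
    sel = times >= stim_time_s - 1e-9
    if epoch_end_s is not None:
        sel &= times < epoch_end_s + 1e-9
    idx = np.nonzero(sel & (x > threshold))[0]
    if idx.size == 0:
        return CENSORED
    i = int(idx[0])
    t_cross = times[i]
    if interpolate and i > 0 and x[i - 1] <= threshold:
        frac = (threshold - x[i - 1]) / (x[i] - x[i - 1])
        t_cross = times[i - 1] + frac / fs
    return float(max(t_cross - stim_time_s, 0.0))


def identify_first_responder(t25_by_stimulus: pd.DataFrame | Mapping) -> str:
    """Identify the first responder from per-stimulus T25 latencies.

    ``t25_by_stimulus``: rows = cells, columns = stimuli, NaN = censored.
    The first responder is the cell with the smallest mean T25 over the
    stimuli it responded to, with cells that responded to *every* stimulus
    strictly preceding partial responders (a fast average computed on an
    incomplete set does not outrank a complete one).  Ties break on the T25
    at the first stimulus, then on the lexicographically smallest cell id.
    """
    df = pd.DataFrame(t25_by_stimulus)
    if df.shape[1] < 1 or df.shape[0] < 2:
        raise ValidationError("need >=1 stimulus and >=2 cells")
    n_censored = df.isna().sum(axis=1)
    if (n_censored == df.shape[1]).all():
        raise NoResponseError("all cells censored in all stimuli")
    mean_t25 = df.mean(axis=1, skipna=True)
    first_stim = df.iloc[:, 0]

    def sort_key(cell: str):
        nc = int(n_censored[cell])
        m = mean_t25[cell]
        f = first_stim[cell]
        return (
            nc if nc > 0 else -1,  # full responders (0 censored) come first
            math.inf if math.isnan(m) else m,
            math.inf if pd.isna(f) else f,
            str(cell),
        )

    ranked = sorted(df.index, key=sort_key)
    return str(ranked[0])


def compute_auc(
    baseline_norm_trace,
    stim_time_s: float,
    window_frames: int = 250,
    fs: float | None = None,
    t0: float | None = None,
) -> tuple[float, bool]:
    """Strength of response: trapezoidal integral of the baseline-normalized
    trace over ``window_frames`` frames after the stimulus, in
    normalized·seconds.

    Returns ``(auc, truncated)`` where ``truncated`` flags a window clipped
    by the end of the recording.  A window of *w* frames spans ``w / fs``
    seconds (w trapezoid intervals, w + 1 samples).
    """
    if isinstance(baseline_norm_trace, NormalizedTrace):
        fs = baseline_norm_trace.fs if fs is None else fs
        t0 = baseline_norm_trace.t0 if t0 is None else t0
    if fs is None:
        raise ValidationError("fs required when passing a bare array")
    t0 = 0.0 if t0 is None else t0
    x = _as_values(baseline_norm_trace)
    i0 = max(int(np.ceil((stim_time_s - t0) * fs - 1e-9)), 0)
    if i0 >= x.size:
        raise ProtocolError(f"stimulus at {stim_time_s} s lies after the last frame")
    i1 = i0 + int(window_frames)
    truncated = i1 >= x.size
    i1 = min(i1, x.size - 1)
    seg = x[i0 : i1 + 1]
    auc = float(np.trapezoid(seg, dx=1.0 / fs))
    return auc, truncated


def compute_fmax(baseline_norm_trace) -> float:
    """Session maximum of the baseline-normalized trace."""
    return float(np.max(_as_values(baseline_norm_trace)))


@dataclass(frozen=True)
class PhaseMetrics:
    amplitude: float
    width_s: float
    n_peaks: int = 1
    empty: bool = False  # second phase with no detected peaks


def _active_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs of True."""
    runs = []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for a, b in zip(edges[::2], edges[1::2]):
        runs.append((int(a), int(b)))
    return runs


def phase_peak_metrics(
    baseline_norm_trace,
    phase_window: tuple[float, float],
    phase: Literal["first", "second"],
    fs: float | None = None,
    t0: float | None = None,
    active_frac: float = 0.25,
    peak_min_sep_s: float = 10.0,
    peak_prominence_frac: float = 0.1,
) -> PhaseMetrics:
    """Peak amplitude and width within a response-phase window.

    First phase: amplitude is the window maximum of the baseline-normalized
    trace; width is the total time spent *active*, i.e. above
    ``active_frac`` of the within-window maximum.  Second phase: calcium
    peaks are detected (local maxima above the active threshold with a
    minimum separation and prominence) and the mean peak maximum and mean
    per-peak active duration are returned; zero peaks yields ``(0, 0)``
    flagged ``empty``.
    """
    if isinstance(baseline_norm_trace, NormalizedTrace):
        fs = baseline_norm_trace.fs if fs is None else fs
        t0 = baseline_norm_trace.t0 if t0 is None else t0
    if fs is None:
        raise ValidationError("fs required when passing a bare array")
    t0 = 0.0 if t0 is None else t0
    x = _as_values(baseline_norm_trace)
    times = t0 + np.arange(x.size) / fs
    a, b = phase_window
    sel = (times >= a - 1e-9) & (times <= b + 1e-9)
    if not np.any(sel):
        raise ProtocolError(f"phase window [{a}, {b}] s contains no frames")
    seg = x[sel]
    phase_max = float(np.max(seg))
    if phase_max <= 0:
        return PhaseMetrics(0.0, 0.0, 0, empty=(phase == "second"))
    thr = active_frac * phase_max
    above = seg > thr
    if phase == "first":
        width = float(np.count_nonzero(above)) / fs
        return PhaseMetrics(phase_max, width, 1, False)
    # second phase: per-peak statistics
    distance = max(1, int(round(peak_min_sep_s * fs)))
    peaks, _props = find_peaks(
        seg, height=thr, distance=distance, prominence=peak_prominence_frac * phase_max
    )
    if peaks.size == 0:
        return PhaseMetrics(0.0, 0.0, 0, empty=True)
    runs = _active_runs(above)
    widths = []
    for p in peaks:
        for r0, r1 in runs:
            if r0 <= p < r1:
                widths.append((r1 - r0) / fs)
                break
    return PhaseMetrics(
        float(np.mean(seg[peaks])), float(np.mean(widths)), int(peaks.size), False
    )


# ---------------------------------------------------------------------------
# table-level API


@dataclass(frozen=True)
class ResponseConfig:
    """Tunable parameters of the response-metrics stage."""

    t25_threshold: float = 0.25
    interpolate_t25: bool = False
    auc_window_frames: int = 250
    active_frac: float = 0.25
    phase1_duration_s: float = 180.0
    peak_min_sep_s: float = 10.0
    peak_prominence_frac: float = 0.1
    #: min-max reference scope: per-stimulus epoch when the protocol has
    #: several stimuli (each injection analyzed separately), else the whole
    #: session; "epoch"/"global" force one or the other.
    minmax_scope: Literal["auto", "epoch", "global"] = "auto"
    #: minimum second-phase window length for phase-2 metrics to be computed
    min_phase2_s: float = 30.0


def build_response_table(
    traces: TraceMatrix,
    protocol: StimulusProtocol,
    config: ResponseConfig | None = None,
) -> pd.DataFrame:
    """Compute the full per-(cell, stimulus) response table.

    Columns: ``cell_id, stimulus, stim_time_s, t25_s, censored, auc,
    auc_truncated, fmax, phase1_amp, phase1_width_s, phase2_mean_amp,
    phase2_mean_width_s, phase2_n_peaks``.
    """
    cfg = config or ResponseConfig()
    glucose = protocol.glucose_events
    if not glucose:
        raise ProtocolError("protocol contains no glucose event")
    t_last = float(traces.times[-1])
    scope = cfg.minmax_scope
    if scope == "auto":
        scope = "epoch" if len(glucose) > 1 else "global"
    rows = []
    for cell in traces.cell_ids:
        raw = traces.trace(cell)
        bl = normalize_baseline(raw, traces.fs, traces.t0, cell)
        fmax = compute_fmax(bl)
        for k, ev in enumerate(glucose):
            t_a, t_b = protocol.epoch_for(ev, t_last)
            if scope == "epoch":
                i_a, i_b = traces.frame_at(t_a), traces.frame_at(t_b)
                window = slice(i_a, max(i_b, i_a + 2))
            else:
                window = None
            mm = normalize_minmax(raw, traces.fs, traces.t0, cell, window=window)
            t25 = compute_t25(
                mm,
                ev.t_start,
                epoch_end_s=t_b,
                threshold=cfg.t25_threshold,
                interpolate=cfg.interpolate_t25,
            )
            auc, trunc = compute_auc(bl, ev.t_start, cfg.auc_window_frames)
            p1_end = min(ev.t_start + cfg.phase1_duration_s, t_b)
            p1 = phase_peak_metrics(
                bl, (ev.t_start, p1_end), "first", active_frac=cfg.active_frac
            )
            if t_b - p1_end >= cfg.min_phase2_s:
                p2 = phase_peak_metrics(
                    bl,
                    (p1_end, t_b),
                    "second",
                    active_frac=cfg.active_frac,
                    peak_min_sep_s=cfg.peak_min_sep_s,
                    peak_prominence_frac=cfg.peak_prominence_frac,
                )
                p2_amp, p2_w, p2_n = p2.amplitude, p2.width_s, p2.n_peaks
            else:
                p2_amp = p2_w = math.nan
                p2_n = 0
            rows.append(
                {
                    "cell_id": cell,
                    "stimulus": k,
                    "stim_time_s": ev.t_start,
                    "t25_s": t25,
                    "censored": bool(math.isnan(t25)),
                    "auc": auc,
                    "auc_truncated": trunc,
                    "fmax": fmax,
                    "phase1_amp": p1.amplitude,
                    "phase1_width_s": p1.width_s,
                    "phase2_mean_amp": p2_amp,
                    "phase2_mean_width_s": p2_w,
                    "phase2_n_peaks": p2_n,
                }
            )
    return pd.DataFrame(rows)


def first_responder_from_table(table: pd.DataFrame) -> str:
    """First responder from a response table produced by
    :func:`build_response_table`."""
    pivot = table.pivot(index="cell_id", columns="stimulus", values="t25_s")
    return identify_first_responder(pivot)
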