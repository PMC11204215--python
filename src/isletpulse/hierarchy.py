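"""Scoring of single-cell optogenetic activation experiments.

Depolarizing one beta cell with a targeted light pulse can recruit a variable
share of the islet: some cells barely move their neighbours, others ignite
most of the imaging plane.  This module detects which non-illuminated cells
*co-activate* (a sustained rise of the calcium signal over their pre-event
baseline), converts the co-activated count into a recruitment fraction, bins
cells into a low / mid / high hierarchy (<25%, 25-75%, >75% of eligible
cells), and correlates recruitment with glucose-response latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

from .errors import DegenerateFitError, ProtocolError, ValidationError
from .io import StimulusEvent, TraceMatrix
from .spatial import LatencyRegression

__all__ = [
    "CoactivationResult",
    "detect_coactivation",
    "classify_hierarchy",
    "hierarchy_latency_correlation",
]


@dataclass(frozen=True)
class CoactivationResult:
    illuminated_cell: str
    coactivated: frozenset[str]
    fraction: float  # co-activated / eligible, in [0, 1]
    bin: Literal["low", "mid", "high"]
    rise_threshold: float
    min_sustain_s: float


def detect_coactivation(
    traces: TraceMatrix,
    protocol_event: StimulusEvent,
    rise_threshold: float = 0.40,
    min_sustain_s: float = 5.0,
    baseline_s: float = 7.5,
    post_window_s: float = 22.5,
) -> CoactivationResult:
    """Detect cells co-activated by a single-cell illumination event.

    A non-illuminated cell is co-activated iff its signal, expressed as a
    relative rise over its own pre-event baseline (mean of the
    ``baseline_s`` seconds before the event), stays >= ``rise_threshold``
    (inclusive) for at least ``min_sustain_s`` contiguous seconds anywhere
    within [event start, event end + ``post_window_s``].  Eligible cells are
    all cells except the illuminated one.
    """
    if protocol_event.kind != "illumination":
        raise ProtocolError("co-activation is defined for illumination events")
    target = str(protocol_event.target_cell)
    if target not in traces.cell_ids:
        raise ProtocolError(f"illuminated cell {target!r} not in trace matrix")
    times = traces.times
    t_on, t_off = protocol_event.t_start, float(protocol_event.t_end)
    base_sel = (times >= t_on - baseline_s - 1e-9) & (times < t_on - 1e-9)
    if not np.any(base_sel):
        raise ProtocolError(
            f"no baseline frames before the illumination at {t_on} s"
        )
    win_sel = (times >= t_on - 1e-9) & (times <= t_off + post_window_s + 1e-9)
    need = max(1, int(math.ceil(min_sustain_s * traces.fs - 1e-9)))
    coactivated: set[str] = set()
    for cell in traces.cell_ids:
        if cell == target:
            continue
        x = traces.trace(cell)
        base = float(np.mean(x[base_sel]))
        if base <= 0:
            continue  # cannot define a relative rise
        rel = (x[win_sel] - base) / base
        above = rel >= rise_threshold - 1e-12
        # longest contiguous run of frames above threshold
        run = best = 0
        for flag in above:
            run = run + 1 if flag else 0
            best = max(best, run)
        if best >= need:
            coactivated.add(cell)
    eligible = traces.n_cells - 1
    if eligible < 1:
        raise ValidationError("need at least one non-illuminated cell")
    fraction = len(coactivated) / eligible
    return CoactivationResult(
        illuminated_cell=target,
        coactivated=frozenset(coactivated),
        fraction=fraction,
        bin=classify_hierarchy(fraction),
        rise_threshold=rise_threshold,
        min_sustain_s=min_sustain_s,
    )


def classify_hierarchy(fraction: float) -> Literal["low", "mid", "high"]:
    """Hierarchy bin from the recruitment fraction.

    low: < 25% of eligible cells; mid: 25-75% (inclusive); high: > 75%.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction < 0.25:
        return "low"
    if fraction <= 0.75:
        return "mid"
    return "high"


def hierarchy_latency_correlation(
    fractions: Mapping[str, float],
    t25_means: Mapping[str, float],
) -> LatencyRegression:
    """OLS of co-activation fraction on mean glucose-response latency T25.

    Tests whether faster responders recruit more of the islet.  Cells
    missing either measurement are dropped; fewer than 3 remaining cells or
    a constant predictor raise :class:`DegenerateFitError`.
    """
    cells = [
        c
        for c in fractions
        if c in t25_means
        and np.isfinite(fractions[c])
        and np.isfinite(t25_means[c])
    ]
    if len(cells) < 3:
        raise DegenerateFitError(
            f"need >=3 cells with both measurements, got {len(cells)}"
        )
    x = np.array([t25_means[c] for c in cells], dtype=float)
    y = np.array([fractions[c] for c in cells], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant latency predictor")
    from scipy import stats

    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 0.0
    return LatencyRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_cells=len(cells),
        mode="time",
    )
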