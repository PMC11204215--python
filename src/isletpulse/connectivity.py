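"""Pearson-correlation functional connectivity between beta cells.

Traces are first denoised with a centred rolling average whose window is a
fixed fraction (default 5%) of the recording length, then the Pearson
correlation R is computed for every unordered cell pair over a response-phase
window (the autocorrelation diagonal is excluded).  Two summary statistics
follow the conventions of islet connectivity studies:

* ``mean_positive_r`` — the mean over all pairs with R > 0;
* ``connected_fraction`` — the percentage of *connected cells*.  A cell
  counts as connected when its mean pairwise R exceeds a threshold
  (default 0.2); a per-pair variant (connected if any pair exceeds the
  threshold) is available via ``cell_rule="any_pair"``.

Connectivity line maps draw an edge for every pair with R >= 0.1, colour
binned on the fixed blue/green/yellow/red ramp used for islet maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import IsletGeometry, TraceMatrix

__all__ = [
    "ConnectivityResult",
    "ConnectivityMap",
    "rolling_smooth",
    "smooth_traces",
    "pearson_matrix",
    "connected_stats",
    "build_connectivity_map",
    "analyze_connectivity",
    "COLOR_BINS",
]

#: colour ramp for connectivity maps.  The printed bin labels
#: (0.1-0.25, 0.26-0.5, 0.51-0.75, 0.76-1.0) describe two-decimal rounding;
#: the continuous half-open boundaries below reproduce that assignment.
COLOR_BINS: tuple[tuple[float, float, str], ...] = (
    (0.10, 0.255, "blue"),
    (0.255, 0.505, "green"),
    (0.505, 0.755, "yellow"),
    (0.755, 1.0 + 1e-12, "red"),
)


@dataclass(frozen=True)
class ConnectivityResult:
    cell_ids: tuple[str, ...]
    r_matrix: np.ndarray  # symmetric, NaN diagonal
    mean_positive_r: float  # NaN if no positive pair
    connected_fraction: float  # percent of cells, 0..100
    phase: str = "whole"
    threshold: float = 0.2
    smoothing_window_frames: int = 1
    n_undefined_cells: int = 0  # zero-variance cells whose pairs are NaN


@dataclass(frozen=True)
class ConnectivityMap:
    edges: pd.DataFrame  # cell_i, cell_j, r, color_bin
    cell_ids: tuple[str, ...]
    coords: np.ndarray


def rolling_smooth(trace: np.ndarray, window_frac: float = 0.05) -> np.ndarray:
    """Centred moving average with window ``max(1, round(frac * N))`` frames.

    Edge frames average over the available (shrunken) window, so a constant
    trace is returned unchanged and the output has the input's length.
    """
    if not 0 < window_frac < 1:
        raise ValidationError(f"window_frac must lie in (0, 1), got {window_frac}")
    x = np.asarray(trace, dtype=float)
    w = max(1, int(round(window_frac * x.size)))
    return (
        pd.Series(x).rolling(window=w, center=True, min_periods=1).mean().to_numpy()
    )


def smooth_traces(traces: TraceMatrix, window_frac: float = 0.05) -> TraceMatrix:
    """Apply :func:`rolling_smooth` to every cell of a trace matrix."""
    sm = np.column_stack(
        [rolling_smooth(traces.values[:, j], window_frac) for j in range(traces.n_cells)]
    )
    return TraceMatrix(traces.cell_ids, sm, traces.fs, traces.t0)


def pearson_matrix(
    traces: TraceMatrix,
    phase_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Pairwise Pearson R over a phase window; diagonal is NaN.

    Cells with zero variance inside the window get NaN against every
    partner (undefined correlation) rather than a fabricated 0.
    """
    if traces.n_cells < 2:
        raise ValidationError("need >=2 cells for a correlation matrix")
    x = traces.values
    if phase_window is not None:
        times = traces.times
        a, b = phase_window
        sel = (times >= a - 1e-9) & (times <= b + 1e-9)
        x = x[sel]
    if x.shape[0] < 3:
        raise ValidationError("phase window must contain at least 3 frames")
    sd = x.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.asarray(r, dtype=float)
    r[sd == 0, :] = math.nan
    r[:, sd == 0] = math.nan
    np.fill_diagonal(r, math.nan)
    return np.clip(r, -1.0, 1.0)


def connected_stats(
    r_matrix: np.ndarray,
    threshold: float = 0.2,
    cell_rule: Literal["mean", "any_pair"] = "mean",
) -> tuple[float, float]:
    """Summary statistics of a pairwise correlation matrix.

    Returns ``(mean_positive_r, connected_fraction)``.  ``mean_positive_r``
    averages all unordered pairs with R > 0 (NaN if none).  A cell is
    *connected* when its mean pairwise R (rule ``"mean"``) or any single
    pair (rule ``"any_pair"``) exceeds ``threshold``; the fraction is in
    percent of cells.  Undefined (NaN) pairs are excluded from all means.
    """
    r = np.asarray(r_matrix, dtype=float)
    n = r.shape[0]
    iu = np.triu_indices(n, k=1)
    pairs = r[iu]
    pos = pairs[np.isfinite(pairs) & (pairs > 0)]
    mean_pos = float(np.mean(pos)) if pos.size else math.nan
    connected = 0
    for i in range(n):
        row = np.delete(r[i], i)
        row = row[np.isfinite(row)]
        if row.size == 0:
            continue
        if cell_rule == "mean":
            if float(np.mean(row)) > threshold:
                connected += 1
        else:
            if float(np.max(row)) > threshold:
                connected += 1
    return mean_pos, 100.0 * connected / n


def _color_bin(r: float) -> str | None:
    for lo, hi, name in COLOR_BINS:
        if lo <= r < hi:
            return name
    return None


def build_connectivity_map(
    r_matrix: np.ndarray,
    cell_ids: tuple[str, ...],
    geometry: IsletGeometry,
) -> ConnectivityMap:
    """Edge list for a connectivity line map: pairs with R >= 0.1, colour
    binned on the fixed ramp."""
    coords = np.array([geometry.coord(c) for c in cell_ids])
    rows = []
    n = len(cell_ids)
    for i in range(n):
        for j in range(i + 1, n):
            r = r_matrix[i, j]
            if not np.isfinite(r):
                continue
            color = _color_bin(float(r))
            if color is None:
                continue
            rows.append(
                {"cell_i": cell_ids[i], "cell_j": cell_ids[j], "r": float(r), "color_bin": color}
            )
    edges = pd.DataFrame(rows, columns=["cell_i", "cell_j", "r", "color_bin"])
    return ConnectivityMap(edges=edges, cell_ids=cell_ids, coords=coords)


def plot_connectivity_map(cmap: ConnectivityMap, ax=None):
    """Render the line map (straight edges coloured by bin) with matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 5))
    index = {c: i for i, c in enumerate(cmap.cell_ids)}
    for _, e in cmap.edges.iterrows():
        pi, pj = cmap.coords[index[e.cell_i]], cmap.coords[index[e.cell_j]]
        ax.plot([pi[0], pj[0]], [pi[1], pj[1]], color=e.color_bin, lw=1, alpha=0.7)
    ax.scatter(cmap.coords[:, 0], cmap.coords[:, 1], s=40, c="k", zorder=3)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_aspect("equal")
    return ax


def analyze_connectivity(
    traces: TraceMatrix,
    phase_window: tuple[float, float] | None = None,
    phase: str = "whole",
    threshold: float = 0.2,
    window_frac: float = 0.05,
    cell_rule: Literal["mean", "any_pair"] = "mean",
) -> ConnectivityResult:
    """Smooth, correlate and summarize in one call.

    Smoothing is applied once to the whole recording (window = ``window_frac``
    of the total frame count) before restricting to the phase window.
    """
    sm = smooth_traces(traces, window_frac)
    r = pearson_matrix(sm, phase_window)
    mean_pos, frac = connected_stats(r, threshold, cell_rule)
    sd = sm.values.std(axis=0)
    return ConnectivityResult(
        cell_ids=traces.cell_ids,
        r_matrix=r,
        mean_positive_r=mean_pos,
        connected_fraction=frac,
        phase=phase,
        threshold=threshold,
        smoothing_window_frames=max(1, int(round(window_frac * traces.n_frames))),
        n_undefined_cells=int(np.count_nonzero(sd == 0)),
    )
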