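"""Latency-versus-distance analysis of the calcium wave.

When a glucose bolus reaches an islet, the first responder fires and the
activity spreads outward, so a cell's onset latency should grow with its
Euclidean distance from the first responder.  This module quantifies that
with an ordinary least-squares regression of latency (seconds, or activation
rank) on distance, reporting slope, intercept and the coefficient of
determination R^2 per islet, plus a mean +/- SD aggregate across islets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, ValidationError
from .io import IsletGeometry

__all__ = [
    "LatencyRegression",
    "distances_to_cell",
    "latency_distance_regression",
    "aggregate_regressions",
]


@dataclass(frozen=True)
class LatencyRegression:
    """OLS fit of latency on distance for one islet."""

    slope: float  # s/um (mode=time) or rank/um (mode=rank)
    intercept: float
    r_squared: float
    n_cells: int
    n_censored: int = 0
    mode: Literal["time", "rank"] = "time"


def distances_to_cell(geometry: IsletGeometry, ref_cell: str) -> dict[str, float]:
    """Euclidean distance (um) from ``ref_cell`` to every cell, itself included."""
    ref = geometry.coord(ref_cell)  # raises KeyError on unknown id
    d = np.linalg.norm(geometry.coords - ref, axis=1)
    return {cid: float(di) for cid, di in zip(geometry.cell_ids, d)}


def latency_distance_regression(
    t25_per_cell: Mapping[str, float],
    distances: Mapping[str, float],
    mode: Literal["time", "rank"] = "time",
) -> LatencyRegression:
    """Regress per-cell response latency on distance to the first responder.

    Censored cells (NaN latency) are excluded from the fit and counted in
    ``n_censored``.  ``mode="rank"`` replaces latencies by their activation
    order (average ranks on ties) before fitting, matching analyses that
    plot temporal order rather than seconds.
    """
    cells = [c for c in t25_per_cell if c in distances]
    lat = np.array([t25_per_cell[c] for c in cells], dtype=float)
    dist = np.array([distances[c] for c in cells], dtype=float)
    keep = np.isfinite(lat)
    n_censored = int(np.count_nonzero(~keep))
    lat, dist = lat[keep], dist[keep]
    if lat.size < 3:
        raise DegenerateFitError(
            f"need >=3 responding cells for a latency regression, got {lat.size}"
        )
    if np.ptp(dist) == 0:
        raise DegenerateFitError("all distances equal; regression undefined")
    y = stats.rankdata(lat) if mode == "rank" else lat
    res = stats.linregress(dist, y)
    r2 = float(res.rvalue**2)
    if np.ptp(y) == 0:  # constant response times: define R^2 = 0
        r2 = 0.0
    return LatencyRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_cells=int(lat.size),
        n_censored=n_censored,
        mode=mode,
    )


def aggregate_regressions(
    fits: Sequence[LatencyRegression],
) -> tuple[float, float]:
    """Mean and sample SD of R^2 across islets.

    With a single fit the SD is undefined and reported as NaN.
    """
    if len(fits) == 0:
        raise ValueError("no regressions to aggregate")
    r2 = np.array([f.r_squared for f in fits], dtype=float)
    mean = float(np.mean(r2))
    sd = float(np.std(r2, ddof=1)) if r2.size > 1 else math.nan
    return mean, sd
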