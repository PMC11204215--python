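"""Model / Results interface tying the analysis stages together.

:class:`IsletModel` is built from data (a trace matrix, a stimulus protocol
and optionally the islet geometry) plus the stage parameters; calling
:meth:`IsletModel.fit` runs every applicable stage — response metrics,
first-responder identification, latency-distance regression, Pearson
connectivity and, when the protocol contains single-cell illumination
events, the co-activation hierarchy — and returns an
:class:`IsletResults` carrying the estimates, a ``summary()`` table and
report serialization.  Constructors from files and from the synthetic
islet simulator are provided.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import ConnectivityResult, analyze_connectivity
from .errors import DegenerateFitError, NoResponseError, ProtocolError
from .hierarchy import CoactivationResult, detect_coactivation, hierarchy_latency_correlation
from .io import IsletGeometry, StimulusProtocol, TraceMatrix, read_geometry, read_protocol, read_trace_table
from .response import ResponseConfig, build_response_table, first_responder_from_table
from .spatial import LatencyRegression, distances_to_cell, latency_distance_regression

__all__ = ["IsletModel", "IsletResults"]


@dataclass(frozen=True)
class IsletResults:
    """Fitted per-islet results.

    Attributes are ``None`` when the corresponding stage was not applicable
    (e.g. no geometry -> no latency regression; no illumination events ->
    no hierarchy).
    """

    response_table: pd.DataFrame | None
    first_responder: str | None
    latency_fit_time: LatencyRegression | None
    latency_fit_rank: LatencyRegression | None
    connectivity: dict[str, ConnectivityResult]
    coactivation: list[CoactivationResult]
    hierarchy_fit: LatencyRegression | None
    params: dict
    seed: int | None = None

    # -- derived accessors ---------------------------------------------------

    @property
    def mean_t25(self) -> float:
        """Mean T25 (s) over all responding (cell, stimulus) pairs."""
        if self.response_table is None:
            return math.nan
        return float(self.response_table["t25_s"].mean(skipna=True))

    def t25_means_by_cell(self) -> dict[str, float]:
        if self.response_table is None:
            return {}
        s = self.response_table.groupby("cell_id")["t25_s"].mean()
        return {str(k): float(v) for k, v in s.items()}

    @property
    def hierarchy_bins(self) -> dict[str, int]:
        counts = {"low": 0, "mid": 0, "high": 0}
        for c in self.coactivation:
            counts[c.bin] += 1
        return counts

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Islet calcium-response analysis",
            "=" * 46,
            f"isletpulse {__version__}" + (f"   seed {self.seed}" if self.seed is not None else ""),
        ]
        if self.response_table is not None:
            n_cells = self.response_table["cell_id"].nunique()
            n_stim = self.response_table["stimulus"].nunique()
            censored = int(self.response_table["censored"].sum())
            lines += [
                "",
                f"Response metrics ({n_cells} cells x {n_stim} stimuli)",
                "-" * 46,
                f"  mean T25             {self.mean_t25:10.3f} s   ({censored} censored)",
                f"  mean AUC             {self.response_table['auc'].mean():10.3f} norm*s",
                f"  mean Fmax            {self.response_table['fmax'].mean():10.3f}",
                f"  first responder      {self.first_responder}",
            ]
        for label, fit in (("time", self.latency_fit_time), ("rank", self.latency_fit_rank)):
            if fit is not None:
                lines += [
                    "",
                    f"Latency vs distance ({label} mode, n={fit.n_cells}, "
                    f"{fit.n_censored} censored)",
                    "-" * 46,
                    f"  slope                {fit.slope:10.4f}",
                    f"  intercept            {fit.intercept:10.3f}",
                    f"  R^2                  {fit.r_squared:10.3f}",
                ]
        for phase, conn in self.connectivity.items():
            lines += [
                "",
                f"Connectivity ({phase} phase, threshold {conn.threshold}, "
                f"smoothing {conn.smoothing_window_frames} frames)",
                "-" * 46,
                f"  mean positive R      {conn.mean_positive_r:10.3f}",
                f"  connected cells      {conn.connected_fraction:10.1f} %",
            ]
        if self.coactivation:
            bins = self.hierarchy_bins
            lines += [
                "",
                f"Optogenetic hierarchy ({len(self.coactivation)} illuminated cells)",
                "-" * 46,
                f"  low (<25%)           {bins['low']:6d}",
                f"  mid (25-75%)         {bins['mid']:6d}",
                f"  high (>75%)          {bins['high']:6d}",
            ]
            if self.hierarchy_fit is not None:
                lines.append(
                    f"  fraction~T25 R^2     {self.hierarchy_fit.r_squared:10.3f}"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def fit_dict(f: LatencyRegression | None):
            return None if f is None else dataclasses.asdict(f)

        conn = {
            phase: {
                "mean_positive_r": c.mean_positive_r,
                "connected_fraction": c.connected_fraction,
                "threshold": c.threshold,
                "smoothing_window_frames": c.smoothing_window_frames,
                "n_undefined_cells": c.n_undefined_cells,
            }
            for phase, c in self.connectivity.items()
        }
        return {
            "version": __version__,
            "seed": self.seed,
            "params": self.params,
            "params_hash": hashlib.sha256(
                json.dumps(self.params, sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
            "mean_t25_s": None if math.isnan(self.mean_t25) else self.mean_t25,
            "first_responder": self.first_responder,
            "latency_fit_time": fit_dict(self.latency_fit_time),
            "latency_fit_rank": fit_dict(self.latency_fit_rank),
            "connectivity": conn,
            "hierarchy_bins": self.hierarchy_bins if self.coactivation else None,
            "coactivation_fractions": {
                c.illuminated_cell: c.fraction for c in self.coactivation
            },
            "hierarchy_fit": fit_dict(self.hierarchy_fit),
        }

    def save(self, outdir: str | Path) -> None:
        """Write report.json, report.md and the response table CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = _jsonable(self.to_dict())
        (outdir / "report.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        (outdir / "report.md").write_text("```\n" + self.summary() + "\n```\n")
        if self.response_table is not None:
            self.response_table.to_csv(
                outdir / "response_table.csv", index=False, float_format="%.17g"
            )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


class IsletModel:
    """Analysis model for one islet recording.

    Parameters
    ----------
    traces : TraceMatrix
    protocol : StimulusProtocol
    geometry : IsletGeometry, optional
        Needed for the latency-distance regression and connectivity maps.
    response_config : ResponseConfig, optional
    connectivity_threshold : float
        Connected-cell Pearson threshold (default 0.2).
    smoothing_frac : float
        Rolling-average window as a fraction of total frames (default 0.05).
    phase1_duration_s : float
        First-phase window length after glucose onset (default 180 s).
    """

    def __init__(
        self,
        traces: TraceMatrix,
        protocol: StimulusProtocol,
        geometry: IsletGeometry | None = None,
        response_config: ResponseConfig | None = None,
        connectivity_threshold: float = 0.2,
        smoothing_frac: float = 0.05,
        phase1_duration_s: float = 180.0,
        rise_threshold: float = 0.40,
        min_sustain_s: float = 5.0,
        seed: int | None = None,
    ) -> None:
        self.traces = traces
        self.protocol = protocol
        self.geometry = geometry
        self.response_config = response_config or ResponseConfig(
            phase1_duration_s=phase1_duration_s
        )
        self.connectivity_threshold = connectivity_threshold
        self.smoothing_frac = smoothing_frac
        self.phase1_duration_s = phase1_duration_s
        self.rise_threshold = rise_threshold
        self.min_sustain_s = min_sustain_s
        self.seed = seed
        self.truth = None  # populated by from_simulation

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        traces_path: str | Path,
        protocol_path: str | Path,
        geometry_path: str | Path | None = None,
        **kwargs,
    ) -> "IsletModel":
        return cls(
            traces=read_trace_table(traces_path),
            protocol=read_protocol(protocol_path),
            geometry=read_geometry(geometry_path) if geometry_path else None,
            **kwargs,
        )

    @classmethod
    def from_simulation(
        cls, scenario_name: str, seed: int = 0, model_kwargs: dict | None = None, **overrides
    ) -> "IsletModel":
        """Simulate a scenario and wrap the output in a model; the ground
        truth is attached as ``model.truth``."""
        from .simulate import scenario, simulate_islet

        cfg = scenario(scenario_name, seed=seed, **overrides)
        traces, geometry, protocol, truth = simulate_islet(cfg)
        model = cls(traces, protocol, geometry, seed=seed, **(model_kwargs or {}))
        model.truth = truth
        return model

    # -- fitting -------------------------------------------------------------

    def _phase_windows(self) -> dict[str, tuple[float, float] | None]:
        """Analysis windows: whole recording, and first/second phase when the
        protocol has a mouse-style single long glucose stimulus."""
        windows: dict[str, tuple[float, float] | None] = {"whole": None}
        glucose = self.protocol.glucose_events
        t_last = float(self.traces.times[-1])
        if len(glucose) == 1:
            ev = glucose[0]
            _, t_end = self.protocol.epoch_for(ev, t_last)
            p1_end = min(ev.t_start + self.phase1_duration_s, t_end)
            windows["first"] = (ev.t_start, p1_end)
            if t_end - p1_end > 30.0:
                windows["second"] = (p1_end, t_end)
        elif glucose:
            # repeated boluses: first-phase window of the first epoch
            ev = glucose[0]
            _, t_end = self.protocol.epoch_for(ev, t_last)
            windows["first"] = (ev.t_start, min(ev.t_start + self.phase1_duration_s, t_end))
        return windows

    def fit(self) -> IsletResults:
        """Run every applicable analysis stage and return the results."""
        glucose = self.protocol.glucose_events
        table = None
        fr = None
        fit_time = fit_rank = None
        if glucose:
            table = build_response_table(self.traces, self.protocol, self.response_config)
            try:
                fr = first_responder_from_table(table)
            except NoResponseError:
                fr = None
            if fr is not None and self.geometry is not None:
                dists = distances_to_cell(self.geometry, fr)
                t25 = self.t25_means(table)
                try:
                    fit_time = latency_distance_regression(t25, dists, mode="time")
                    fit_rank = latency_distance_regression(t25, dists, mode="rank")
                except DegenerateFitError:
                    fit_time = fit_rank = None

        connectivity: dict[str, ConnectivityResult] = {}
        for phase, window in self._phase_windows().items():
            try:
                connectivity[phase] = analyze_connectivity(
                    self.traces,
                    phase_window=window,
                    phase=phase,
                    threshold=self.connectivity_threshold,
                    window_frac=self.smoothing_frac,
                )
            except Exception:
                continue

        coact: list[CoactivationResult] = []
        for ev in self.protocol.illumination_events:
            try:
                coact.append(
                    detect_coactivation(
                        self.traces,
                        ev,
                        rise_threshold=self.rise_threshold,
                        min_sustain_s=self.min_sustain_s,
                    )
                )
            except ProtocolError:
                continue

        hier_fit = None
        if coact and table is not None:
            fractions = {c.illuminated_cell: c.fraction for c in coact}
            t25 = self.t25_means(table)
            try:
                hier_fit = hierarchy_latency_correlation(fractions, t25)
            except DegenerateFitError:
                hier_fit = None

        return IsletResults(
            response_table=table,
            first_responder=fr,
            latency_fit_time=fit_time,
            latency_fit_rank=fit_rank,
            connectivity=connectivity,
            coactivation=coact,
            hierarchy_fit=hier_fit,
            params=self._params(),
            seed=self.seed,
        )

    @staticmethod
    def t25_means(table: pd.DataFrame) -> dict[str, float]:
        s = table.groupby("cell_id")["t25_s"].mean()
        return {str(k): float(v) for k, v in s.items()}

    def _params(self) -> dict:
        return {
            "response_config": dataclasses.asdict(self.response_config),
            "connectivity_threshold": self.connectivity_threshold,
            "smoothing_frac": self.smoothing_frac,
            "phase1_duration_s": self.phase1_duration_s,
            "rise_threshold": self.rise_threshold,
            "min_sustain_s": self.min_sustain_s,
            "n_cells": self.traces.n_cells,
            "n_frames": self.traces.n_frames,
            "fs": self.traces.fs,
        }
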