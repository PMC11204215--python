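"""Core containers and file I/O for calcium-trace analysis.

The three domain objects — :class:`TraceMatrix` (frames x cells fluorescence),
:class:`IsletGeometry` (cell centroids in micrometres) and
:class:`StimulusProtocol` (glucose / illumination / KCl events) — are plain
dataclasses validated on construction.  File formats are deliberately simple
and text based:

* trace tables: CSV with a leading ``# isletpulse`` metadata comment carrying
  the sampling rate, a ``time_s`` column and one column per cell;
* geometry: CSV of ``cell_id, x_um, y_um[, z_um]``;
* protocols and results: JSON.

Traces can also be extracted from a grayscale image stack (frames x H x W)
given either an integer label mask or disc ROIs, by mean pixel intensity.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    GeometryError,
    ParseError,
    ProtocolError,
    ValidationError,
)

__all__ = [
    "TraceMatrix",
    "IsletGeometry",
    "StimulusEvent",
    "StimulusProtocol",
    "read_trace_table",
    "write_trace_table",
    "read_geometry",
    "write_geometry",
    "read_protocol",
    "write_protocol",
    "extract_traces",
    "write_results",
    "read_results",
]

_META_RE = re.compile(r"#\s*isletpulse\s+(.*)")


@dataclass(frozen=True)
class TraceMatrix:
    """Per-cell fluorescence time series.

    Parameters
    ----------
    cell_ids : sequence of str
        Unique, ordered cell identifiers (column order of ``values``).
    values : ndarray, shape (n_frames, n_cells)
        Raw fluorescence in arbitrary units.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Time of frame 0 in seconds.
    """

    cell_ids: tuple[str, ...]
    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D (frames x cells), got {values.ndim}-D")
        if values.shape[0] < 2:
            raise ValidationError("a trace matrix needs at least 2 frames")
        if values.shape[1] != len(self.cell_ids):
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids but {values.shape[1]} trace columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids must be unique")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite fluorescence at frame {bad[0]}, cell {self.cell_ids[bad[1]]}"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.t0 + np.arange(self.n_frames) / self.fs

    def cell_index(self, cell_id: str) -> int:
        try:
            return self.cell_ids.index(str(cell_id))
        except ValueError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None

    def trace(self, cell_id: str) -> np.ndarray:
        """Return one cell's trace as a 1-D array."""
        return self.values[:, self.cell_index(cell_id)]

    def frame_at(self, t: float) -> int:
        """Index of the first frame at or after time ``t`` (seconds)."""
        idx = int(np.ceil((t - self.t0) * self.fs - 1e-9))
        return max(idx, 0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.cell_ids))
        df.insert(0, "time_s", self.times)
        return df


@dataclass(frozen=True)
class IsletGeometry:
    """Cell centroids in micrometres (2-D or 3-D)."""

    cell_ids: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValidationError("coords must have shape (n_cells, 2) or (n_cells, 3)")
        if coords.shape[0] != len(self.cell_ids):
            raise ValidationError("cell_ids and coords disagree in length")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids must be unique")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coordinates must be finite")

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]

    def coord(self, cell_id: str) -> np.ndarray:
        try:
            i = self.cell_ids.index(str(cell_id))
        except ValueError:
            raise KeyError(f"unknown cell id {cell_id!r}") from None
        return self.coords[i]


VALID_EVENT_KINDS = ("glucose", "illumination", "kcl")


@dataclass(frozen=True)
class StimulusEvent:
    kind: str
    t_start: float
    t_end: float | None = None
    target_cell: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in VALID_EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "illumination":
            if self.t_end is None or self.t_end <= self.t_start:
                raise ValidationError("illumination events need t_end > t_start")
            if self.target_cell is None:
                raise ValidationError("illumination events must name a target cell")
        elif self.target_cell is not None:
            raise ValidationError(f"{self.kind} events carry no target cell")


@dataclass(frozen=True)
class StimulusProtocol:
    """Time-ordered stimulus events plus the pre-stimulus baseline window."""

    events: tuple[StimulusEvent, ...]
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        events = tuple(self.events)
        object.__setattr__(self, "events", events)
        starts = [e.t_start for e in events]
        if starts != sorted(starts):
            raise ValidationError("events must be time-ordered")
        if self.baseline_window is not None:
            a, b = self.baseline_window
            object.__setattr__(self, "baseline_window", (float(a), float(b)))
            if b <= a:
                raise ValidationError("baseline window must have positive length")
            if events and b > events[0].t_start + 1e-9:
                raise ValidationError("baseline must precede the first stimulus")

    @property
    def glucose_events(self) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind == "glucose")

    @property
    def illumination_events(self) -> tuple[StimulusEvent, ...]:
        return tuple(e for e in self.events if e.kind == "illumination")

    @property
    def kcl_time(self) -> float | None:
        for e in self.events:
            if e.kind == "kcl":
                return e.t_start
        return None

    def epoch_for(self, event: StimulusEvent, t_last: float) -> tuple[float, float]:
        """Analysis epoch of ``event``: from its start to the next event or ``t_last``."""
        end = t_last
        for other in self.events:
            if other.t_start > event.t_start + 1e-9:
                end = min(end, other.t_start)
                break
        if event.t_start > t_last:
            raise ProtocolError(
                f"stimulus at {event.t_start} s lies after the recording end ({t_last} s)"
            )
        return (event.t_start, end)


# ---------------------------------------------------------------------------
# trace tables


def write_trace_table(traces: TraceMatrix, path: str | Path) -> None:
    """Write a trace table as CSV with an ``# isletpulse`` metadata line."""
    path = Path(path)
    df = traces.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# isletpulse fs_hz={traces.fs!r} t0_s={traces.t0!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_trace_table(path: str | Path, fs: float | None = None) -> TraceMatrix:
    """Read a CSV/TSV trace table into a :class:`TraceMatrix`.

    The sampling rate is taken from the ``# isletpulse fs_hz=...`` header
    line, or from the ``fs`` argument; with neither, :class:`ConfigError`.
    A ``time_s`` or ``frame`` first column is accepted; remaining columns are
    cells in file order.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    with open(path) as fh:
        first = fh.readline()
    m = _META_RE.match(first)
    if m:
        for tok in m.group(1).split():
            key, _, val = tok.partition("=")
            try:
                meta[key] = float(val)
            except ValueError:
                raise ParseError(f"bad metadata token {tok!r} in {path}") from None
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # check the raw header before pandas mangles duplicate column names
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = [h.strip() for h in line.rstrip("\n").split(sep)]
                if len(set(header)) != len(header):
                    raise ValidationError(f"{path}: duplicate cell IDs in header")
                break
    df = pd.read_csv(path, comment="#", sep=sep)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected a time/frame column plus >=1 cell column")
    time_col = df.columns[0]
    cells = df.columns[1:]
    if len(set(cells)) != len(cells):
        raise ValidationError(f"{path}: duplicate cell IDs in header")
    vals = df[cells]
    non_numeric = vals.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    if non_numeric.isna().any().any():
        col = non_numeric.columns[non_numeric.isna().any()][0]
        row = int(non_numeric[col].isna().idxmax())
        raise ParseError(f"{path}: non-numeric or missing value at row {row}, column {col!r}")
    fs_val = fs if fs is not None else meta.get("fs_hz")
    if fs_val is None:
        # last resort: infer from a time column in seconds
        if time_col.lower() in ("time_s", "time", "t_s") and len(df) >= 2:
            dt = np.diff(df[time_col].to_numpy())
            if np.allclose(dt, dt[0]) and dt[0] > 0:
                fs_val = 1.0 / float(dt[0])
    if fs_val is None:
        raise ConfigError(f"{path}: sampling rate not in header metadata and not supplied")
    t0 = meta.get("t0_s", float(df[time_col].iloc[0]) if "time" in time_col.lower() else 0.0)
    return TraceMatrix(
        cell_ids=tuple(str(c) for c in cells),
        values=non_numeric.to_numpy(dtype=float),
        fs=float(fs_val),
        t0=float(t0),
    )


# ---------------------------------------------------------------------------
# geometry


def write_geometry(geometry: IsletGeometry, path: str | Path) -> None:
    cols = ["x_um", "y_um", "z_um"][: geometry.coords.shape[1]]
    df = pd.DataFrame(geometry.coords, columns=cols)
    df.insert(0, "cell_id", list(geometry.cell_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def read_geometry(path: str | Path) -> IsletGeometry:
    df = pd.read_csv(path, comment="#")
    if "cell_id" not in df.columns:
        raise ParseError(f"{path}: geometry CSV needs a cell_id column")
    coord_cols = [c for c in ("x_um", "y_um", "z_um") if c in df.columns]
    if len(coord_cols) < 2:
        raise ParseError(f"{path}: geometry CSV needs x_um and y_um columns")
    return IsletGeometry(
        cell_ids=tuple(str(c) for c in df["cell_id"]),
        coords=df[coord_cols].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# protocols


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    payload = {
        "schema": "isletpulse-protocol-1",
        "baseline_window": list(protocol.baseline_window) if protocol.baseline_window else None,
        "events": [
            {k: v for k, v in dataclasses.asdict(e).items() if v is not None}
            for e in protocol.events
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_protocol(path: str | Path) -> StimulusProtocol:
    payload = json.loads(Path(path).read_text())
    try:
        events = tuple(StimulusEvent(**e) for e in payload["events"])
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: malformed protocol JSON: {exc}") from exc
    bw = payload.get("baseline_window")
    return StimulusProtocol(events=events, baseline_window=tuple(bw) if bw else None)


# ---------------------------------------------------------------------------
# ROI extraction


def _disc_mask(shape: tuple[int, int], x: float, y: float, radius: float) -> np.ndarray:
    from skimage.draw import disk

    rr, cc = disk((y, x), radius, shape=None)
    if rr.size == 0:
        raise GeometryError(f"empty ROI at ({x}, {y}) r={radius}")
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= shape[0] or cc.max() >= shape[1]:
        raise GeometryError(f"ROI at ({x}, {y}) r={radius} extends outside the image")
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def extract_traces(
    stack: np.ndarray,
    rois: np.ndarray | Sequence[tuple],
    fs: float,
    t0: float = 0.0,
) -> TraceMatrix:
    """Extract mean-intensity traces from an image stack.

    Parameters
    ----------
    stack : ndarray, shape (frames, H, W)
        Grayscale image stack.
    rois : label mask or sequence of (id, x, y, radius)
        Either an integer label image (same H x W; label 0 = background) or
        disc ROIs given by centre (x, y) in pixel coordinates and radius.
    fs : float
        Sampling rate in Hz.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValidationError("stack must be (frames, H, W)")
    shape = stack.shape[1:]
    masks: list[np.ndarray] = []
    ids: list[str] = []
    if isinstance(rois, np.ndarray) and rois.ndim == 2:
        if rois.shape != shape:
            raise GeometryError(
                f"label mask shape {rois.shape} does not match frames {shape}"
            )
        for label in np.unique(rois):
            if label == 0:
                continue
            mask = rois == label
            masks.append(mask)
            ids.append(str(int(label)))
        if not masks:
            raise GeometryError("label mask contains no ROI (all background)")
    else:
        for roi in rois:
            cid, x, y, radius = roi
            masks.append(_disc_mask(shape, float(x), float(y), float(radius)))
            ids.append(str(cid))
        if not masks:
            raise GeometryError("no ROIs supplied")
    flat = stack.reshape(stack.shape[0], -1)
    values = np.column_stack([flat[:, m.ravel()].mean(axis=1) for m in masks])
    return TraceMatrix(cell_ids=tuple(ids), values=values, fs=fs, t0=t0)


# ---------------------------------------------------------------------------
# results


def write_results(result, path: str | Path) -> None:
    """Serialize a result object (DataFrame -> CSV, mapping/dataclass -> JSON)."""
    path = Path(path)
    if isinstance(result, pd.DataFrame):
        result.to_csv(path, index=False, float_format="%.17g")
        return
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        payload = dataclasses.asdict(result)
    elif isinstance(result, dict):
        payload = result
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    payload = _jsonify(payload)
    payload.setdefault("schema", "isletpulse-result-1")
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_results(path: str | Path):
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    return pd.read_csv(path, comment="#")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.integer):
        return int(obj)
    return obj
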