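"""Plain-text readers and writers for every pipeline schema.

All data travel as CSV/JSON for diffability:

traces CSV
    columns ``frame, shaft, spine_001, …`` (raw fluorescence per frame),
    with a ``<stem>.meta.json`` sidecar carrying the frame rate, generator
    parameters and ground truth when simulated.
population CSV
    columns ``session_day, spine_id, position_um, head_diam, neck_diam,
    head_fluor, neck_fluor, has_head``.
events CSV
    columns ``dendrite_id, roi_id, onset_frame, offset_frame, peak_dff,
    source``.

A read-only TIFF ingestion path extracts mean-ROI traces from a
multi-frame stack given a JSON list of ellipse/polygon ROIs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spinedyn.events import EventCall, FluorescenceTrace, RoiTraceSet
from spinedyn.turnover import SpineObservation, TurnoverInterval

__all__ = [
    "SchemaError",
    "write_trace_set",
    "read_traces",
    "write_population",
    "read_population",
    "write_events",
    "write_turnover",
    "write_results",
    "read_tiff_traces",
]

POPULATION_COLUMNS = [
    "session_day",
    "spine_id",
    "position_um",
    "head_diam",
    "neck_diam",
    "head_fluor",
    "neck_fluor",
]


class SchemaError(ValueError):
    """A file does not conform to one of the documented schemas."""


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def write_trace_set(
    traces: RoiTraceSet,
    path: str | Path,
    params: dict | None = None,
    ground_truth: dict | None = None,
) -> Path:
    """Write a trace set as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    data = {"frame": np.arange(traces.n_frames), "shaft": traces.shaft.values}
    for name, tr in traces.spines.items():
        data[name] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)
    meta = {
        "dendrite_id": traces.dendrite_id,
        "frame_rate_hz": traces.shaft.frame_rate_hz,
        "kind": traces.shaft.kind,
    }
    if params is not None:
        meta["params"] = params
    if ground_truth is not None:
        meta["ground_truth"] = ground_truth
    _meta_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_traces(
    path: str | Path, frame_rate_hz: float | None = None
) -> RoiTraceSet:
    """Read a trace-set CSV (and its sidecar, when present) back into memory."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except ValueError as exc:
        raise SchemaError(f"{path}: not a parseable CSV ({exc})") from exc
    meta: dict = {}
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())
    if frame_rate_hz is None:
        frame_rate_hz = meta.get("frame_rate_hz")
    if frame_rate_hz is None:
        raise SchemaError(
            f"{path}: no frame rate; supply frame_rate_hz or a .meta.json sidecar"
        )
    if "shaft" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'shaft'")
    spine_cols = [c for c in df.columns if c.startswith("spine")]
    if not spine_cols:
        raise SchemaError(f"{path}: no spine columns (named 'spine_*')")
    for col in ["shaft"] + spine_cols:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0] + 2}"
            )
    kind = meta.get("kind", "raw")
    shaft = FluorescenceTrace(df["shaft"].to_numpy(), frame_rate_hz, kind)
    spines = {
        c: FluorescenceTrace(df[c].to_numpy(), frame_rate_hz, kind)
        for c in spine_cols
    }
    return RoiTraceSet(shaft, spines, dendrite_id=meta.get("dendrite_id", path.stem))


def write_population(
    sessions: list[list[SpineObservation]], path: str | Path
) -> Path:
    """Write longitudinal spine observations as one long-format CSV."""
    path = Path(path)
    rows = []
    for session in sessions:
        for o in session:
            rows.append(
                {
                    "session_day": o.session_day,
                    "spine_id": o.spine_id,
                    "position_um": o.position_um,
                    "head_diam": o.head_diam,
                    "neck_diam": o.neck_diam,
                    "head_fluor": o.head_fluor,
                    "neck_fluor": o.neck_fluor,
                    "has_head": o.has_head,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_population(path: str | Path) -> list[list[SpineObservation]]:
    """Read a population CSV into per-session observation lists.

    Sessions are ordered by ``session_day``.  Row-level validation failures
    (nonpositive diameters or fluorescences, negative positions) are
    reported with their 1-based CSV line number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in POPULATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column {missing[0]!r}")
    if "has_head" not in df.columns:
        df["has_head"] = True
    sessions: dict[int, list[SpineObservation]] = {}
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            obs = SpineObservation(
                spine_id=int(row["spine_id"]),
                session_day=int(row["session_day"]),
                position_um=float(row["position_um"]),
                head_diam=float(row["head_diam"]),
                neck_diam=float(row["neck_diam"]),
                head_fluor=float(row["head_fluor"]),
                neck_fluor=float(row["neck_fluor"]),
                has_head=bool(row["has_head"]),
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: invalid record at line {line}: {exc}") from exc
        sessions.setdefault(obs.session_day, []).append(obs)
    return [sessions[day] for day in sorted(sessions)]


def write_events(
    events_by_roi: dict[str, list[EventCall]],
    path: str | Path,
    dendrite_id: str = "dendrite",
) -> Path:
    """Write detected events as CSV (one row per event)."""
    path = Path(path)
    rows = [
        {
            "dendrite_id": dendrite_id,
            "roi_id": roi,
            "onset_frame": ev.onset_frame,
            "offset_frame": ev.offset_frame,
            "peak_dff": ev.peak_dff,
            "source": ev.source,
        }
        for roi, events in events_by_roi.items()
        for ev in events
    ]
    cols = ["dendrite_id", "roi_id", "onset_frame", "offset_frame", "peak_dff", "source"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def write_turnover(
    intervals: list[TurnoverInterval],
    path: str | Path,
    dendrite_id: str = "dendrite",
    start_days: list[int] | None = None,
) -> Path:
    """Write per-interval turnover counts and rates as CSV."""
    path = Path(path)
    rows = []
    for i, iv in enumerate(intervals):
        rows.append(
            {
                "dendrite_id": dendrite_id,
                "interval_start_day": start_days[i] if start_days else 1 + 2 * i,
                "n_before": iv.n_before,
                "n_after": iv.n_after,
                "n_generated": iv.n_generated,
                "n_eliminated": iv.n_eliminated,
                "gen_rate_pct": iv.gen_rate_pct,
                "elim_rate_pct": iv.elim_rate_pct,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_results(objects: dict, path: str | Path) -> dict:
    """Write a dict of JSON-serializable results; returns a small manifest."""
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(objects, indent=1, sort_keys=True, default=default))
    return {"path": str(path), "keys": sorted(objects)}


# ---------------------------------------------------------------------------
# optional TIFF ingestion


def _roi_mask(roi: dict, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import ellipse as draw_ellipse
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros(shape, dtype=bool)
    kind = roi.get("type")
    if kind == "ellipse":
        rr, cc = draw_ellipse(
            roi["center_row"], roi["center_col"], roi["radius_row"],
            roi["radius_col"], shape=shape,
        )
    elif kind == "polygon":
        verts = np.asarray(roi["vertices"], dtype=float)
        rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    else:
        raise SchemaError(f"unknown ROI type {kind!r} for roi {roi.get('id')!r}")
    mask[rr, cc] = True
    if not mask.any():
        raise SchemaError(f"ROI {roi.get('id')!r} covers no pixels")
    return mask


def read_tiff_traces(
    tiff_path: str | Path,
    roi_path: str | Path,
    frame_rate_hz: float,
    background: float = 0.0,
) -> RoiTraceSet:
    """Extract mean-ROI raw traces from a multi-frame TIFF stack.

    ``roi_path`` is a JSON list of ROI dicts.  Exactly one ROI must have
    ``"role": "shaft"`` (typically a polygon over the dendritic shaft); the
    rest are spine ROIs (typically ovals over individual spines).
    """
    import tifffile

    stack = tifffile.imread(str(tiff_path))
    if stack.ndim == 2:
        stack = stack[None, :, :]
    if stack.ndim != 3:
        raise SchemaError(f"{tiff_path}: expected a (frames, y, x) stack")
    rois = json.loads(Path(roi_path).read_text())
    shaft_rois = [r for r in rois if r.get("role") == "shaft"]
    if len(shaft_rois) != 1:
        raise SchemaError(
            f"{roi_path}: need exactly one ROI with role 'shaft', found {len(shaft_rois)}"
        )
    shape = stack.shape[1:]
    flat = stack.reshape(stack.shape[0], -1).astype(float) - background

    def mean_trace(roi: dict) -> np.ndarray:
        mask = _roi_mask(roi, shape).ravel()
        return flat[:, mask].mean(axis=1)

    shaft = FluorescenceTrace(mean_trace(shaft_rois[0]), frame_rate_hz, "raw")
    spines = {
        str(r.get("id", f"spine_{i + 1:03d}")): FluorescenceTrace(
            mean_trace(r), frame_rate_hz, "raw"
        )
        for i, r in enumerate(r for r in rois if r.get("role") != "shaft")
    }
    if not spines:
        raise SchemaError(f"{roi_path}: no spine ROIs")
    return RoiTraceSet(shaft, spines, dendrite_id=Path(tiff_path).stem)
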