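"""Calcium-transient analysis of ROI fluorescence traces.

Implements the trace-analysis chain used for spine calcium imaging:

1. ΔF/F₀ per ROI, with F₀ the mode of the fluorescence histogram over the
   imaging session (robust to sparse transients).
2. Shaft-transient detection: maximal runs of frames exceeding
   ``sd_multiplier`` robust standard deviations for at least
   ``min_run_frames`` consecutive frames.
3. Spine-specific transient isolation: the shaft trace is scaled as much as
   possible into each spine trace (nonnegative least squares over
   shaft-event frames), and events are detected in the residual with the
   same threshold rule.  A spine exceeding the scaled dendritic signal on
   at least ``active_spine_min_exceedances`` discrete occasions is an
   active spine.
4. Dendrite classification into three patterns: dendritic + synaptic
   transients, dendritic transients only, or no transients.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DetectionParams",
    "FluorescenceTrace",
    "RoiTraceSet",
    "EventCall",
    "DendriteClass",
    "BaselineError",
    "estimate_mode_baseline",
    "compute_dff",
    "detect_shaft_events",
    "is_active_shaft",
    "fit_shaft_scale",
    "classify_spine",
    "classify_dendrite",
    "summarize_classification",
    "classification_percentages",
    "robust_sd",
]

MIN_FRAMES = 10


class BaselineError(ValueError):
    """Raised when a baseline F₀ is nonpositive or cannot be estimated."""


@dataclass(frozen=True)
class DetectionParams:
    """Constants of the event-detection chain.

    Parameters
    ----------
    sd_multiplier
        Threshold in units of the robust SD of the analyzed trace
        (default 3: transients must cross three standard deviations).
    min_run_frames
        Minimum run length, in frames, for a suprathreshold excursion to
        count as a transient (default 3: strictly more than two
        consecutive frames).
    active_spine_min_exceedances
        Minimum number of residual (spine-specific) events for a spine to
        be called active (default 4: strictly more than three occasions).
    mode_bin_rule
        Histogram binning rule for the mode baseline ("fd" =
        Freedman–Diaconis).
    mode_min_bins
        Lower bound on the number of histogram bins for the mode baseline.
    """

    sd_multiplier: float = 3.0
    min_run_frames: int = 3
    active_spine_min_exceedances: int = 4
    mode_bin_rule: str = "fd"
    mode_min_bins: int = 20

    def __post_init__(self) -> None:
        if not (self.sd_multiplier > 0):
            raise ValueError("sd_multiplier must be > 0")
        if self.min_run_frames < 1:
            raise ValueError("min_run_frames must be >= 1")
        if self.active_spine_min_exceedances < 1:
            raise ValueError("active_spine_min_exceedances must be >= 1")
        if self.mode_bin_rule != "fd":
            raise ValueError(f"unknown mode_bin_rule {self.mode_bin_rule!r}")
        if self.mode_min_bins < 1:
            raise ValueError("mode_min_bins must be >= 1")


@dataclass
class FluorescenceTrace:
    """A single-ROI time series, raw fluorescence or ΔF/F₀.

    ``values`` holds one sample per imaging frame; ``kind`` distinguishes
    raw fluorescence ("raw") from baseline-normalized ΔF/F₀ ("dff").
    """

    values: np.ndarray
    frame_rate_hz: float
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if self.values.size < MIN_FRAMES:
            raise ValueError(
                f"trace too short: {self.values.size} frames (< {MIN_FRAMES})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if not (self.frame_rate_hz > 0):
            raise ValueError("frame_rate_hz must be > 0")
        if self.kind not in ("raw", "dff"):
            raise ValueError(f"kind must be 'raw' or 'dff', got {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass
class RoiTraceSet:
    """One dendrite's ROI bundle: a shaft trace plus named spine traces."""

    shaft: FluorescenceTrace
    spines: dict[str, FluorescenceTrace]
    dendrite_id: str = "dendrite"

    def __post_init__(self) -> None:
        if len(self.spines) < 1:
            raise ValueError("a trace set requires at least one spine ROI")
        n = self.shaft.n_frames
        rate = self.shaft.frame_rate_hz
        for name, tr in self.spines.items():
            if tr.n_frames != n:
                raise ValueError(
                    f"spine {name!r} has {tr.n_frames} frames, shaft has {n}"
                )
            if tr.frame_rate_hz != rate:
                raise ValueError(f"spine {name!r} frame rate differs from shaft")

    @property
    def n_frames(self) -> int:
        return self.shaft.n_frames


@dataclass(frozen=True)
class EventCall:
    """One detected transient as a half-open frame interval [onset, offset)."""

    onset_frame: int
    offset_frame: int
    peak_dff: float
    source: str = "shaft"  # "shaft" or "spine_specific"

    def __post_init__(self) -> None:
        if self.offset_frame <= self.onset_frame:
            raise ValueError("offset_frame must exceed onset_frame")
        if not (self.peak_dff > 0):
            raise ValueError("peak_dff must be > 0")
        if self.source not in ("shaft", "spine_specific"):
            raise ValueError(f"unknown event source {self.source!r}")

    @property
    def n_frames(self) -> int:
        return self.offset_frame - self.onset_frame


class DendriteClass(enum.Enum):
    """The three activity patterns of an imaged dendrite."""

    DENDRITIC_PLUS_SYNAPTIC = "dendritic_plus_synaptic"
    DENDRITIC_ONLY = "dendritic_only"
    NONE = "none"


def robust_sd(values: np.ndarray) -> float:
    """Robust standard deviation, 1.4826 × median absolute deviation.

    Approximates the noise SD of a trace when transients are sparse, since
    the median is insensitive to a small fraction of event frames.  Falls
    back to the sample SD when the MAD is exactly zero (more than half of
    the samples identical) but the trace is not constant.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    sd = 1.4826 * mad
    if sd == 0.0:
        sd = float(np.std(values))
    return float(sd)


def estimate_mode_baseline(
    trace: FluorescenceTrace | np.ndarray,
    params: DetectionParams | None = None,
) -> float:
    """Baseline F₀ as the mode of the fluorescence histogram.

    The histogram uses Freedman–Diaconis bin widths with a floor of
    ``params.mode_min_bins`` bins over the data range; F₀ is the center of
    the most populated bin, ties broken toward the lower bin.  A constant
    trace returns its value directly.
    """
    params = params or DetectionParams()
    values = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, dtype=float)
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        return lo
    n = values.size
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    fd_width = 2.0 * iqr / n ** (1.0 / 3.0)
    if fd_width > 0:
        n_bins = max(params.mode_min_bins, math.ceil((hi - lo) / fd_width))
    else:
        n_bins = params.mode_min_bins
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    best = int(np.argmax(counts))  # argmax takes the first (lower) bin on ties
    return float(0.5 * (edges[best] + edges[best + 1]))


def compute_dff(
    trace: FluorescenceTrace,
    params: DetectionParams | None = None,
    background: float = 0.0,
) -> FluorescenceTrace:
    """Convert a raw trace to ΔF/F₀ = (F − F₀)/F₀ with a mode baseline.

    ``background`` is an optional scalar background level subtracted from
    every frame before baseline estimation (background subtraction precedes
    normalization in the imaging pipeline).
    """
    if trace.kind != "raw":
        raise ValueError("compute_dff expects a raw-fluorescence trace")
    f = trace.values - background
    f0 = estimate_mode_baseline(f, params)
    if f0 <= 0:
        raise BaselineError(
            f"nonpositive baseline F0={f0:g}; raw trace appears corrupt"
        )
    return FluorescenceTrace((f - f0) / f0, trace.frame_rate_hz, kind="dff")


def _suprathreshold_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open [start, stop) index pairs."""
    padded = np.concatenate(([False], above, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def detect_events(
    dff: FluorescenceTrace,
    params: DetectionParams | None = None,
    source: str = "shaft",
) -> list[EventCall]:
    """Detect transients in a ΔF/F trace.

    A transient is a maximal run of at least ``min_run_frames`` consecutive
    frames whose value exceeds ``sd_multiplier`` × robust SD of the trace.
    Returns disjoint events sorted by onset.  A constant trace (SD zero)
    yields no events.
    """
    params = params or DetectionParams()
    if dff.kind != "dff":
        raise ValueError("event detection expects a dff trace")
    sigma = robust_sd(dff.values)
    if sigma == 0.0:
        return []
    threshold = params.sd_multiplier * sigma
    events = []
    for start, stop in _suprathreshold_runs(dff.values > threshold):
        if stop - start >= params.min_run_frames:
            peak = float(np.max(dff.values[start:stop]))
            events.append(EventCall(start, stop, peak, source=source))
    return events


def detect_shaft_events(
    dff: FluorescenceTrace, params: DetectionParams | None = None
) -> list[EventCall]:
    """Detect dendritic-shaft transients (3-SD / ≥3-frame rule by default)."""
    return detect_events(dff, params, source="shaft")


def is_active_shaft(events: list[EventCall]) -> bool:
    """A shaft is active if it produced one or more transients in the session."""
    return len(events) >= 1


def fit_shaft_scale(
    spine_dff: FluorescenceTrace,
    shaft_dff: FluorescenceTrace,
    shaft_events: list[EventCall] | None = None,
) -> tuple[float, np.ndarray]:
    """Scale the shaft trace as much as possible to fit the spine trace.

    Returns ``(a, residual)`` where ``a ≥ 0`` minimizes
    ``Σ (spine − a·shaft)²`` restricted to frames inside the detected shaft
    events, so the fit is driven by the invading dendritic transients rather
    than by baseline noise.  When no shaft events are supplied the fit uses
    all frames.  The residual ``spine − a·shaft`` spans all frames and
    carries any spine-specific transients.
    """
    s = spine_dff.values
    d = shaft_dff.values
    if s.size != d.size:
        raise ValueError("spine and shaft traces must have equal length")
    if shaft_events:
        mask = np.zeros(d.size, dtype=bool)
        for ev in shaft_events:
            mask[ev.onset_frame : ev.offset_frame] = True
    else:
        mask = np.ones(d.size, dtype=bool)
    denom = float(np.dot(d[mask], d[mask]))
    if denom == 0.0:
        a = 0.0
    else:
        a = max(0.0, float(np.dot(s[mask], d[mask])) / denom)
    return a, s - a * d


def classify_spine(
    spine_dff: FluorescenceTrace,
    shaft_dff: FluorescenceTrace,
    params: DetectionParams | None = None,
    shaft_events: list[EventCall] | None = None,
) -> tuple[bool, list[EventCall]]:
    """Call a spine active or inactive and return its spine-specific events.

    The shaft trace is scaled into the spine trace (``fit_shaft_scale``) and
    transients are detected in the residual with the same threshold rule,
    the SD taken from the residual itself.  The spine is active when the
    residual event count reaches ``active_spine_min_exceedances`` — i.e. its
    calcium transients exceeded the scaled dendritic transients on that many
    discrete occasions.
    """
    params = params or DetectionParams()
    if shaft_events is None:
        shaft_events = detect_shaft_events(shaft_dff, params)
    _, residual = fit_shaft_scale(spine_dff, shaft_dff, shaft_events)
    # a residual that is numerically zero relative to the spine signal is
    # silence, not structure; without this guard the SD-relative threshold
    # would chase floating-point dust after a perfect proportional fit
    span = float(np.ptp(spine_dff.values))
    if robust_sd(residual) <= 1e-12 * span:
        return False, []
    residual_trace = FluorescenceTrace(
        residual, spine_dff.frame_rate_hz, kind="dff"
    )
    spine_events = detect_events(residual_trace, params, source="spine_specific")
    active = len(spine_events) >= params.active_spine_min_exceedances
    return active, spine_events


def classify_dendrite(
    traces: RoiTraceSet, params: DetectionParams | None = None
) -> DendriteClass:
    """Categorize one dendrite by its session activity pattern.

    ``dendritic_plus_synaptic`` if at least one spine is active;
    otherwise ``dendritic_only`` if the shaft is active;
    otherwise ``none``.  Raw trace sets are converted to ΔF/F first.
    """
    params = params or DetectionParams()
    shaft = traces.shaft
    spines = traces.spines
    if shaft.kind == "raw":
        shaft = compute_dff(shaft, params)
        spines = {k: compute_dff(v, params) for k, v in spines.items()}
    shaft_events = detect_shaft_events(shaft, params)
    any_active_spine = any(
        classify_spine(sp, shaft, params, shaft_events)[0]
        for sp in spines.values()
    )
    if any_active_spine:
        return DendriteClass.DENDRITIC_PLUS_SYNAPTIC
    if is_active_shaft(shaft_events):
        return DendriteClass.DENDRITIC_ONLY
    return DendriteClass.NONE


_CLASS_ORDER = [
    DendriteClass.DENDRITIC_PLUS_SYNAPTIC,
    DendriteClass.DENDRITIC_ONLY,
    DendriteClass.NONE,
]


def summarize_classification(
    classes: list[DendriteClass], conditions: list[str]
) -> pd.DataFrame:
    """Tally dendrite classes per condition into a 3 × conditions table.

    Rows are the three activity patterns (in fixed order), columns the
    distinct condition labels in first-appearance order; cells are dendrite
    counts.  Every condition must contribute at least one dendrite.
    """
    if len(classes) != len(conditions):
        raise ValueError("classes and conditions must have equal length")
    if not classes:
        raise ValueError("no dendrites to summarize")
    col_order = list(dict.fromkeys(conditions))
    table = pd.DataFrame(
        0,
        index=[c.value for c in _CLASS_ORDER],
        columns=col_order,
        dtype=int,
    )
    for cls, cond in zip(classes, conditions):
        table.loc[cls.value, cond] += 1
    empty = [c for c in col_order if table[c].sum() == 0]
    if empty:
        raise ValueError(f"condition {empty[0]!r} has no dendrites")
    return table


def classification_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a classification count table to per-condition percentages."""
    totals = table.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"condition {bad!r} has no dendrites")
    return 100.0 * table / totals
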