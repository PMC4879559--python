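"""Synthetic two-photon imaging data with known ground truth.

Two generators make the full analysis chain testable without recordings:

``simulate_trace_set``
    A 4-minute ROI trace bundle for one dendrite.  Dendritic (shaft)
    transients arrive as a Poisson process and invade every spine trace
    (scaled by ``invasion_gain``); sparse spine-specific transients arrive
    independently per spine.  Transients follow a difference-of-exponentials
    kernel normalized to unit peak (GCaMP6s-like kinetics by default).
    Raw fluorescence is ``baseline_f0 × (1 + ΔF/F + noise)``.

``simulate_spine_population``
    Longitudinal spine-observation tables at 2-day intervals.  Session 1
    places spines uniformly along the dendrite; at each interval every spine
    is independently eliminated with probability ``p_elim`` and a
    Binomial(count, ``p_gen``) number of new spines is born at fresh
    positions.  Survivors keep their position up to a small jitter strictly
    below the matching tolerance, and spine ids are never reused, so
    identity ground truth is unambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from spinedyn.events import FluorescenceTrace, RoiTraceSet
from spinedyn.turnover import SpineObservation

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_trace_set",
    "simulate_spine_population",
    "simulate_morphology_profiles",
]

# jitter applied to surviving spine positions between sessions; the SD is
# 0.2 um and draws are truncated at half the 1.0-um matching tolerance
POSITION_JITTER_SD_UM = 0.2
POSITION_JITTER_MAX_UM = 0.5
# new spines are born at least this far from every existing spine
EXCLUSION_ZONE_UM = 1.0


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the synthetic generators.

    Imaging parameters follow the study design the generator emulates:
    4-minute sessions (``duration_s`` = 240) at 10–15 frames/s
    (``frame_rate_hz`` = 12), GCaMP6s-like transient kinetics
    (``kernel_rise_s`` = 0.18 s, ``kernel_decay_s`` = 1.2 s), and 2-day
    turnover intervals with per-interval generation and elimination
    probabilities ``p_gen`` and ``p_elim``.
    """

    frame_rate_hz: float = 12.0
    duration_s: float = 240.0
    shaft_event_rate_hz: float = 0.05
    spine_specific_rate_hz: float = 0.02
    invasion_gain: float = 1.0
    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.2
    amp_shaft: float = 2.0
    amp_spine: float = 1.5
    noise_sd: float = 0.1
    baseline_f0: float = 100.0
    n_spines_per_dendrite: int = 10
    dendrite_length_um: float = 400.0
    p_gen: float = 0.05
    p_elim: float = 0.05
    n_sessions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = [
            "frame_rate_hz",
            "duration_s",
            "shaft_event_rate_hz",
            "spine_specific_rate_hz",
            "invasion_gain",
            "kernel_rise_s",
            "kernel_decay_s",
            "amp_shaft",
            "amp_spine",
            "noise_sd",
            "baseline_f0",
            "dendrite_length_um",
        ]
        for name in nonneg:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v!r}")
        for name in ("p_gen", "p_elim"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_spines_per_dendrite < 1:
            raise ValueError("n_spines_per_dendrite must be >= 1")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    def with_(self, **overrides) -> "SimParams":
        """A copy with the given fields replaced."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Hidden state emitted alongside synthetic data.

    ``spine_fates`` has one entry per interval: a dict with id lists under
    the keys "persist", "eliminated" and "generated".
    ``morphology_labels`` maps spine id to "spine" or "filopodium" for
    morphology fixtures.
    """

    shaft_event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spine_specific_event_times: dict[str, np.ndarray] = field(default_factory=dict)
    spine_fates: list[dict[str, list[int]]] = field(default_factory=list)
    morphology_labels: dict[int, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "shaft_event_times": [float(t) for t in self.shaft_event_times],
            "spine_specific_event_times": {
                k: [float(t) for t in v]
                for k, v in self.spine_specific_event_times.items()
            },
            "spine_fates": self.spine_fates,
            "morphology_labels": {
                str(k): v for k, v in self.morphology_labels.items()
            },
        }


def _transient_kernel(params: SimParams) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, unit peak, at frame rate."""
    dt = 1.0 / params.frame_rate_hz
    t_max = 8.0 * max(params.kernel_decay_s, params.kernel_rise_s, dt)
    t = np.arange(0.0, t_max, dt)
    if params.kernel_rise_s == params.kernel_decay_s:
        # degenerate equal time constants: alpha function t * exp(-t/tau)
        tau = max(params.kernel_decay_s, dt)
        k = t * np.exp(-t / tau)
    else:
        k = np.exp(-t / params.kernel_decay_s) - np.exp(-t / params.kernel_rise_s)
    peak = np.max(k)
    if peak > 0:
        k = k / peak
    else:
        k = np.zeros_like(k)
        k[0] = 1.0
    return k


def _poisson_event_times(
    rng: np.random.Generator, rate_hz: float, duration_s: float
) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _clean_dff(
    event_times: np.ndarray, amp: float, kernel: np.ndarray, params: SimParams
) -> np.ndarray:
    """Clean ΔF/F trace: unit impulses at event frames convolved with kernel."""
    impulses = np.zeros(params.n_frames)
    if event_times.size:
        frames = np.floor(event_times * params.frame_rate_hz).astype(int)
        frames = np.clip(frames, 0, params.n_frames - 1)
        np.add.at(impulses, frames, amp)
    return np.convolve(impulses, kernel)[: params.n_frames]


def simulate_trace_set(params: SimParams) -> tuple[RoiTraceSet, GroundTruth]:
    """Generate one dendrite's raw ROI traces (shaft + spines) with ground truth.

    Every shaft transient appears in every spine trace scaled by
    ``invasion_gain`` (dendritic transients invade the spines); each spine
    additionally receives its own independent spine-specific transients.
    Identical ``params`` (including ``seed``) produce bit-identical output.
    """
    if params.n_frames < 10:
        raise ValueError(
            f"frame_rate_hz x duration_s gives {params.n_frames} frames (< 10)"
        )
    ss = np.random.SeedSequence(params.seed)
    n_spines = params.n_spines_per_dendrite
    streams = [np.random.default_rng(s) for s in ss.spawn(1 + n_spines)]
    shaft_rng, spine_rngs = streams[0], streams[1:]

    kernel = _transient_kernel(params)
    shaft_times = _poisson_event_times(
        shaft_rng, params.shaft_event_rate_hz, params.duration_s
    )
    shaft_clean = _clean_dff(shaft_times, params.amp_shaft, kernel, params)

    def to_raw(clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noise = (
            rng.normal(0.0, params.noise_sd, size=params.n_frames)
            if params.noise_sd > 0
            else 0.0
        )
        return params.baseline_f0 * (1.0 + clean + noise)

    rate = params.frame_rate_hz
    shaft_trace = FluorescenceTrace(to_raw(shaft_clean, shaft_rng), rate, "raw")

    spines: dict[str, FluorescenceTrace] = {}
    spine_event_times: dict[str, np.ndarray] = {}
    for i, rng in enumerate(spine_rngs):
        name = f"spine_{i + 1:03d}"
        own_times = _poisson_event_times(
            rng, params.spine_specific_rate_hz, params.duration_s
        )
        own_clean = _clean_dff(own_times, params.amp_spine, kernel, params)
        clean = params.invasion_gain * shaft_clean + own_clean
        spines[name] = FluorescenceTrace(to_raw(clean, rng), rate, "raw")
        spine_event_times[name] = own_times

    truth = GroundTruth(
        shaft_event_times=shaft_times,
        spine_specific_event_times=spine_event_times,
    )
    return RoiTraceSet(shaft_trace, spines, dendrite_id="sim"), truth


def _draw_spine_morphology(rng: np.random.Generator) -> dict:
    """Head/neck geometry and brightness for a true spine (ratios > 1.2)."""
    neck_diam = rng.uniform(0.15, 0.35)
    head_ratio = rng.uniform(1.3, 2.5)
    neck_fluor = rng.uniform(80.0, 120.0)
    fluor_ratio = rng.uniform(1.3, 3.0)
    return {
        "head_diam": neck_diam * head_ratio,
        "neck_diam": neck_diam,
        "head_fluor": neck_fluor * fluor_ratio,
        "neck_fluor": neck_fluor,
        "has_head": True,
    }


def _draw_filopodium_morphology(rng: np.random.Generator) -> dict:
    """Geometry for a headless filopodial protrusion (ratios <= 1.2)."""
    neck_diam = rng.uniform(0.15, 0.35)
    head_ratio = rng.uniform(0.8, 1.2)
    neck_fluor = rng.uniform(80.0, 120.0)
    fluor_ratio = rng.uniform(0.8, 1.2)
    return {
        "head_diam": neck_diam * head_ratio,
        "neck_diam": neck_diam,
        "head_fluor": neck_fluor * fluor_ratio,
        "neck_fluor": neck_fluor,
        "has_head": False,
    }


def _fresh_position(
    rng: np.random.Generator, existing: list[float], length_um: float
) -> float:
    """Uniform position at least EXCLUSION_ZONE_UM from every existing spine."""
    for _ in range(1000):
        pos = rng.uniform(0.0, length_um)
        if all(abs(pos - p) >= EXCLUSION_ZONE_UM for p in existing):
            return pos
    raise RuntimeError(
        "could not place a new spine; dendrite too crowded for the exclusion zone"
    )


def simulate_spine_population(
    params: SimParams,
) -> tuple[list[list[SpineObservation]], GroundTruth]:
    """Generate longitudinal spine tables under a birth–death turnover model.

    Returns one observation list per session (session days 1, 3, 5, …) and
    a :class:`GroundTruth` whose ``spine_fates`` records, per interval,
    which spine ids persisted, were eliminated, or were generated.
    Eliminated ids are never reused, so matching has an exact answer.
    """
    if params.n_sessions < 2:
        raise ValueError("simulate_spine_population requires n_sessions >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    length = params.dendrite_length_um

    positions: dict[int, float] = {}
    next_id = 0
    for _ in range(params.n_spines_per_dendrite):
        positions[next_id] = _fresh_position(rng, list(positions.values()), length)
        next_id += 1

    def observe(day: int) -> list[SpineObservation]:
        obs = []
        for sid in sorted(positions):
            morph = _draw_spine_morphology(rng)
            obs.append(
                SpineObservation(
                    spine_id=sid,
                    session_day=day,
                    position_um=positions[sid],
                    **morph,
                )
            )
        return obs

    sessions = [observe(1)]
    fates: list[dict[str, list[int]]] = []
    for k in range(1, params.n_sessions):
        ids = sorted(positions)
        eliminated = [sid for sid in ids if rng.random() < params.p_elim]
        survivors = [sid for sid in ids if sid not in set(eliminated)]
        n_new = rng.binomial(len(ids), params.p_gen) if ids else 0
        for sid in eliminated:
            del positions[sid]
        for sid in survivors:
            jitter = np.clip(
                rng.normal(0.0, POSITION_JITTER_SD_UM),
                -POSITION_JITTER_MAX_UM,
                POSITION_JITTER_MAX_UM,
            )
            positions[sid] = float(np.clip(positions[sid] + jitter, 0.0, length))
        generated = []
        for _ in range(n_new):
            positions[next_id] = _fresh_position(
                rng, list(positions.values()), length
            )
            generated.append(next_id)
            next_id += 1
        fates.append(
            {
                "persist": survivors,
                "eliminated": eliminated,
                "generated": generated,
            }
        )
        sessions.append(observe(1 + 2 * k))
    return sessions, GroundTruth(spine_fates=fates)


def simulate_morphology_profiles(
    params: SimParams, fraction_filopodia: float
) -> tuple[list[SpineObservation], GroundTruth]:
    """Generate protrusion records, a mix of true spines and filopodia.

    True spines draw head/neck diameter and fluorescence ratios above 1.2;
    filopodia draw both ratios at or below 1.2 and have no head.  Class
    labels are retained in ``GroundTruth.morphology_labels``.
    """
    if not (0.0 <= fraction_filopodia <= 1.0):
        raise ValueError("fraction_filopodia must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n = params.n_spines_per_dendrite
    obs: list[SpineObservation] = []
    labels: dict[int, str] = {}
    for i in range(n):
        is_filo = rng.random() < fraction_filopodia
        morph = (
            _draw_filopodium_morphology(rng)
            if is_filo
            else _draw_spine_morphology(rng)
        )
        obs.append(
            SpineObservation(
                spine_id=i,
                session_day=1,
                position_um=rng.uniform(0.0, params.dendrite_length_um),
                **morph,
            )
        )
        labels[i] = "filopodium" if is_filo else "spine"
    return obs, GroundTruth(morphology_labels=labels)
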