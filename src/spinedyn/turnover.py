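"""Spine morphology filtering, cross-session matching, and turnover rates.

Protrusions qualify as spines when they have an apparent head structure:
head/neck diameter ratio and head/neck fluorescence ratio both strictly
above 1.2.  Headless filopodia are excluded.  Accepted spines are matched
across successive sessions by their position along the dendrite (1-D
arc-length coordinate relative to stable landmarks); a spine is "the same"
when its position moved less than the matching tolerance.  Generation and
elimination rates are the percentages of spines that appeared and
disappeared between two sessions 2 days apart, with the earlier session's
spine count as the default denominator for both rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpineObservation",
    "MatchResult",
    "TurnoverInterval",
    "GroupSummary",
    "HEAD_NECK_RATIO_THRESHOLD",
    "DEFAULT_TOLERANCE_UM",
    "filter_spines",
    "match_sessions",
    "compute_turnover",
    "aggregate_group",
    "turnover_over_sessions",
]

logger = logging.getLogger(__name__)

HEAD_NECK_RATIO_THRESHOLD = 1.2
DEFAULT_TOLERANCE_UM = 1.0


@dataclass
class SpineObservation:
    """One protrusion observed in one imaging session.

    ``position_um`` is the arc-length coordinate along the dendrite from a
    fixed reference landmark; head/neck diameters are in μm and
    fluorescences in arbitrary units. ``has_head`` records whether a head
    was clearly visible (protrusions emanating perpendicular to the imaging
    plane count only when it was).
    """

    spine_id: int | None
    session_day: int
    position_um: float
    head_diam: float
    neck_diam: float
    head_fluor: float
    neck_fluor: float
    has_head: bool = True

    def __post_init__(self) -> None:
        for name in ("head_diam", "neck_diam", "head_fluor", "neck_fluor"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if self.position_um < 0:
            raise ValueError(f"position_um must be >= 0, got {self.position_um!r}")

    @property
    def diam_ratio(self) -> float:
        return self.head_diam / self.neck_diam

    @property
    def fluor_ratio(self) -> float:
        return self.head_fluor / self.neck_fluor


@dataclass
class MatchResult:
    """Identity correspondence between two successive sessions."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    eliminated_ids: list[int] = field(default_factory=list)
    generated_ids: list[int] = field(default_factory=list)

    @property
    def n_before(self) -> int:
        return len(self.pairs) + len(self.eliminated_ids)

    @property
    def n_after(self) -> int:
        return len(self.pairs) + len(self.generated_ids)


@dataclass(frozen=True)
class TurnoverInterval:
    """Generation/elimination counts and rates for one 2-day interval."""

    n_before: int
    n_after: int
    n_generated: int
    n_eliminated: int
    gen_rate_pct: float
    elim_rate_pct: float


@dataclass(frozen=True)
class GroupSummary:
    """Unweighted mean ± SEM of interval rates; n is the interval count."""

    mean_gen_pct: float
    sem_gen_pct: float
    mean_elim_pct: float
    sem_elim_pct: float
    n_intervals: int


def filter_spines(
    observations: list[SpineObservation],
    ratio_threshold: float = HEAD_NECK_RATIO_THRESHOLD,
) -> list[SpineObservation]:
    """Keep protrusions with an apparent head structure.

    Acceptance requires a visible head and both head/neck diameter and
    head/neck fluorescence ratios strictly above ``ratio_threshold``
    (default 1.2); records at exactly the threshold are rejected.
    """
    return [
        o
        for o in observations
        if o.has_head
        and o.diam_ratio > ratio_threshold
        and o.fluor_ratio > ratio_threshold
    ]


def _check_crowding(observations: list[SpineObservation], tol: float, label: str) -> None:
    pos = sorted(o.position_um for o in observations)
    close = [
        (a, b) for a, b in zip(pos, pos[1:]) if b - a <= tol
    ]
    if close:
        logger.warning(
            "%s session has %d spine pairs closer than the %.2f um matching "
            "tolerance; matching is deterministic but may be ambiguous",
            label,
            len(close),
            tol,
        )


def match_sessions(
    before: list[SpineObservation],
    after: list[SpineObservation],
    tolerance_um: float = DEFAULT_TOLERANCE_UM,
) -> MatchResult:
    """Match spines across two sessions by position along the dendrite.

    Greedy nearest-position matching: candidate pairs with
    ``|Δposition| ≤ tolerance_um`` are accepted in order of increasing
    distance (ties broken by lower before-position, then lower
    after-position), each spine pairing at most once.  Unmatched
    before-spines are eliminated; unmatched after-spines are generated.
    """
    if tolerance_um <= 0:
        raise ValueError("tolerance_um must be > 0")
    for obs_list, label in ((before, "before"), (after, "after")):
        ids = [o.spine_id for o in obs_list]
        if any(i is None for i in ids):
            raise ValueError(f"{label} session has observations without spine_id")
        if len(set(ids)) != len(ids):
            raise ValueError(f"{label} session has duplicate spine ids")
        _check_crowding(obs_list, tolerance_um, label)

    b_pos = np.array([o.position_um for o in before])
    a_pos = np.array([o.position_um for o in after])
    b_ids = [o.spine_id for o in before]
    a_ids = [o.spine_id for o in after]
    if b_pos.size and a_pos.size:
        dist = np.abs(b_pos[:, None] - a_pos[None, :])
        close = np.argwhere(dist <= tolerance_um)
    else:
        close = np.empty((0, 2), dtype=int)
    candidates = sorted(
        (dist[i, j], b_pos[i], a_pos[j], b_ids[i], a_ids[j]) for i, j in close
    )

    used_before: set[int] = set()
    used_after: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, bid, aid in candidates:
        if bid in used_before or aid in used_after:
            continue
        pairs.append((bid, aid))
        used_before.add(bid)
        used_after.add(aid)
    eliminated = [o.spine_id for o in before if o.spine_id not in used_before]
    generated = [o.spine_id for o in after if o.spine_id not in used_after]
    return MatchResult(pairs=pairs, eliminated_ids=eliminated, generated_ids=generated)


def compute_turnover(
    match: MatchResult, gen_denominator: str = "before"
) -> TurnoverInterval:
    """Turnover rates for one matched interval, as percentages.

    Both rates use the earlier session's spine count as denominator by
    default, which keeps elimination a proper fraction and puts both rates
    on one common baseline; set ``gen_denominator="after"`` to express
    generation relative to the later session's count instead.
    """
    if gen_denominator not in ("before", "after"):
        raise ValueError("gen_denominator must be 'before' or 'after'")
    n_before, n_after = match.n_before, match.n_after
    if n_before == 0:
        raise ValueError("turnover rate undefined: no spines in the earlier session")
    n_gen = len(match.generated_ids)
    n_elim = len(match.eliminated_ids)
    gen_denom = n_before if gen_denominator == "before" else n_after
    if gen_denom == 0:
        raise ValueError("generation rate undefined: zero denominator session")
    return TurnoverInterval(
        n_before=n_before,
        n_after=n_after,
        n_generated=n_gen,
        n_eliminated=n_elim,
        gen_rate_pct=100.0 * n_gen / gen_denom,
        elim_rate_pct=100.0 * n_elim / n_before,
    )


def aggregate_group(intervals: list[TurnoverInterval]) -> GroupSummary:
    """Average interval rates within a group (the interval is the unit of
    analysis); SEM uses n−1 degrees of freedom and is 0 for a single
    interval."""
    if not intervals:
        raise ValueError("cannot aggregate an empty interval list")
    gen = np.array([iv.gen_rate_pct for iv in intervals])
    elim = np.array([iv.elim_rate_pct for iv in intervals])
    n = len(intervals)

    def sem(x: np.ndarray) -> float:
        if n < 2:
            return 0.0
        return float(np.std(x, ddof=1) / np.sqrt(n))

    return GroupSummary(
        mean_gen_pct=float(np.mean(gen)),
        sem_gen_pct=sem(gen),
        mean_elim_pct=float(np.mean(elim)),
        sem_elim_pct=sem(elim),
        n_intervals=n,
    )


def turnover_over_sessions(
    sessions: list[list[SpineObservation]],
    tolerance_um: float = DEFAULT_TOLERANCE_UM,
    apply_filter: bool = True,
    gen_denominator: str = "before",
) -> list[TurnoverInterval]:
    """Filter, match and compute turnover for every successive session pair."""
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    kept = [filter_spines(s) if apply_filter else list(s) for s in sessions]
    intervals = []
    for before, after in zip(kept, kept[1:]):
        match = match_sessions(before, after, tolerance_um)
        intervals.append(compute_turnover(match, gen_denominator))
    return intervals
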