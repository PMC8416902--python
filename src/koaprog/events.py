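"""Z-score event bookkeeping for the linear event-based progression model.

A *z-score event* is a biomarker crossing a fixed z-score threshold relative
to a control group; the ordered set of all events defines the stage axis of
the progression model.  This module holds the biomarker definitions (name,
direction of progression, candidate thresholds), the retained event set with
its per-biomarker maximum z-score, and validated event orderings (one
ordering per disease subtype).

Conventions
-----------
* Candidate thresholds default to z = 1, 2, 3, 5.
* A candidate event is retained when strictly more than ``min_count``
  subjects exceed the threshold (default 10).
* The "maximum z-score" of a biomarker — the value its trajectory reaches at
  the final stage — is derived from its largest retained event by the fixed
  mapping 1 -> 2, 2 -> 3, 3 -> 5, 5 -> 7.
* Stages are 0-based: stage 0 means no event has occurred, stage S means all
  S events have occurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CANDIDATE_Z: tuple[float, ...] = (1.0, 2.0, 3.0, 5.0)

#: Largest retained event z -> maximum z-score reached at the final stage.
MAX_Z_MAP: dict[float, float] = {1.0: 2.0, 2.0: 3.0, 3.0: 5.0, 5.0: 7.0}


def max_z_for(largest_event_z: float) -> float:
    """Maximum z-score input implied by a biomarker's largest retained event."""
    try:
        return MAX_Z_MAP[float(largest_event_z)]
    except KeyError:
        raise ValueError(
            f"no maximum z-score defined for largest event z={largest_event_z!r}; "
            f"known events: {sorted(MAX_Z_MAP)}"
        ) from None


@dataclass(frozen=True)
class BiomarkerDef:
    """One biomarker: identity, direction of progression, candidate events.

    Parameters
    ----------
    name
        Column name in the raw measurement table.
    direction
        +1 if the raw measurement increases with disease severity (pain
        scores, osteophyte and sclerosis grades), -1 if it decreases (joint
        space width, cartilage thickness).  Direction -1 biomarkers have
        their z-scores sign-flipped so that every z-score increases with
        severity.
    candidate_events
        Strictly increasing candidate z-score thresholds.
    """

    name: str
    direction: int = 1
    candidate_events: tuple[float, ...] = CANDIDATE_Z

    def __post_init__(self) -> None:
        if self.direction not in (1, -1):
            raise ValueError(f"{self.name}: direction must be +1 or -1, got {self.direction}")
        ev = tuple(float(z) for z in self.candidate_events)
        if len(ev) == 0:
            raise ValueError(f"{self.name}: candidate_events must be non-empty")
        if any(b <= a for a, b in zip(ev, ev[1:])):
            raise ValueError(f"{self.name}: candidate_events must be strictly increasing")
        object.__setattr__(self, "candidate_events", ev)


@dataclass(frozen=True)
class Event:
    """A single z-score event: ``biomarker`` crossing threshold ``z``."""

    biomarker: str
    z: float


@dataclass(frozen=True)
class EventSet:
    """The retained z-score events and per-biomarker maximum z-scores.

    Events are stored grouped by biomarker in ascending threshold order; the
    total event count ``S`` is the number of model stages minus one.
    """

    events: tuple[Event, ...]
    max_z: Mapping[str, float]

    # derived arrays, filled in __post_init__
    biomarkers: tuple[str, ...] = field(init=False, repr=False)
    event_biomarker_idx: np.ndarray = field(init=False, repr=False, compare=False)
    event_z: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise ValueError("event set must contain at least one event")
        names: list[str] = []
        for e in self.events:
            if e.biomarker not in names:
                names.append(e.biomarker)
        per: dict[str, list[float]] = {n: [] for n in names}
        for e in self.events:
            per[e.biomarker].append(float(e.z))
        for n, zs in per.items():
            if any(b <= a for a, b in zip(zs, zs[1:])):
                raise ValueError(f"{n}: event thresholds must be strictly increasing")
            if n not in self.max_z:
                raise ValueError(f"{n}: missing maximum z-score")
            if self.max_z[n] <= zs[-1]:
                raise ValueError(
                    f"{n}: maximum z-score {self.max_z[n]} must exceed the "
                    f"largest event z={zs[-1]}"
                )
        idx = {n: i for i, n in enumerate(names)}
        object.__setattr__(self, "biomarkers", tuple(names))
        object.__setattr__(
            self,
            "event_biomarker_idx",
            np.array([idx[e.biomarker] for e in self.events], dtype=np.intp),
        )
        object.__setattr__(
            self, "event_z", np.array([e.z for e in self.events], dtype=float)
        )

    @property
    def S(self) -> int:
        """Total number of events (the final stage index)."""
        return len(self.events)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    def events_of(self, biomarker: str) -> list[int]:
        """Indices (into ``events``) of one biomarker's events, ascending z."""
        b = self.biomarkers.index(biomarker)
        return [i for i in range(self.S) if self.event_biomarker_idx[i] == b]

    def max_z_array(self) -> np.ndarray:
        return np.array([self.max_z[n] for n in self.biomarkers], dtype=float)


def build_event_set(
    z: pd.DataFrame,
    defs: Sequence[BiomarkerDef],
    candidate_z: Iterable[float] = CANDIDATE_Z,
    min_count: int = 10,
) -> EventSet:
    """Select the z-score events supported by the data.

    For each biomarker, a candidate threshold is retained when at least
    ``min_count`` subjects have a (direction-adjusted) z-score strictly above
    it.  The biomarker's maximum z-score is then set from its largest
    retained event via :data:`MAX_Z_MAP`.

    Parameters
    ----------
    z
        Direction-adjusted z-score table (subjects x biomarkers).
    defs
        Biomarker definitions; every definition's name must be a column of
        ``z``.
    candidate_z
        Global candidate thresholds; intersected with each definition's own
        ``candidate_events``.
    min_count
        Minimum number of subjects strictly above a threshold for the event
        to be retained.

    Raises
    ------
    ValueError
        If a biomarker retains no event (it must be removed from ``defs``
        first), or a definition's column is missing.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    cand = tuple(sorted(float(c) for c in set(candidate_z)))
    events: list[Event] = []
    max_z: dict[str, float] = {}
    for d in defs:
        if d.name not in z.columns:
            raise ValueError(f"biomarker {d.name!r} not found in z-score table")
        col = np.asarray(z[d.name], dtype=float)
        kept = [
            c
            for c in cand
            if c in d.candidate_events and int(np.sum(col > c)) >= min_count
        ]
        if not kept:
            raise ValueError(
                f"biomarker {d.name!r} retains no z-score event at "
                f"min_count={min_count}; remove it before building the event set"
            )
        events.extend(Event(d.name, c) for c in kept)
        max_z[d.name] = max_z_for(kept[-1])
    return EventSet(events=tuple(events), max_z=max_z)


def event_set_from_counts(
    counts: Mapping[str, int] | Sequence[int],
    candidate_z: Sequence[float] = CANDIDATE_Z,
) -> EventSet:
    """Reconstruct an event set from published per-biomarker event counts.

    A biomarker with ``k`` events is assigned the ``k`` lowest candidate
    thresholds (1, 2, ... of the candidate ladder), and its maximum z-score
    follows from the largest of those via the standard mapping.  Useful for
    reproducing event-set bookkeeping (total event count, maximum z-scores)
    when only the counts of a published panel are available.
    """
    if not isinstance(counts, Mapping):
        counts = {f"biomarker_{i + 1:02d}": int(k) for i, k in enumerate(counts)}
    events: list[Event] = []
    max_z: dict[str, float] = {}
    for name, k in counts.items():
        k = int(k)
        if not 1 <= k <= len(candidate_z):
            raise ValueError(f"{name}: event count {k} outside 1..{len(candidate_z)}")
        zs = [float(c) for c in candidate_z[:k]]
        events.extend(Event(name, c) for c in zs)
        max_z[name] = max_z_for(zs[-1])
    return EventSet(events=tuple(events), max_z=max_z)


# ---------------------------------------------------------------------------
# Event sequences


def validate_order(order: Sequence[int], event_set: EventSet) -> np.ndarray:
    """Check that ``order`` is a valid event sequence for ``event_set``.

    Valid means: a permutation of ``0..S-1`` in which the events of each
    biomarker appear in strictly increasing z order.  Returns the order as an
    integer array.
    """
    arr = np.asarray(order, dtype=np.intp)
    S = event_set.S
    if arr.shape != (S,) or not np.array_equal(np.sort(arr), np.arange(S)):
        raise ValueError(f"order must be a permutation of 0..{S - 1}")
    pos = np.empty(S, dtype=np.intp)
    pos[arr] = np.arange(S)
    for b in range(event_set.n_biomarkers):
        evs = np.flatnonzero(event_set.event_biomarker_idx == b)  # ascending z
        if np.any(np.diff(pos[evs]) <= 0):
            raise ValueError(
                f"events of biomarker {event_set.biomarkers[b]!r} must appear "
                "in increasing z order"
            )
    return arr


@dataclass(frozen=True)
class EventSequence:
    """A validated ordering of all events — one subtype's progression course.

    ``order[j]`` is the index (into ``event_set.events``) of the event at
    position ``j + 1``; a subject at stage ``k`` has experienced the first
    ``k`` events of the sequence.
    """

    order: tuple[int, ...]
    event_set: EventSet

    def __post_init__(self) -> None:
        arr = validate_order(self.order, self.event_set)
        object.__setattr__(self, "order", tuple(int(i) for i in arr))

    @property
    def S(self) -> int:
        return self.event_set.S

    def positions(self) -> np.ndarray:
        """1-based position of each event (indexed by event index)."""
        pos = np.empty(self.S, dtype=np.intp)
        pos[np.asarray(self.order, dtype=np.intp)] = np.arange(1, self.S + 1)
        return pos


def random_valid_order(
    event_set: EventSet, rng: np.random.Generator
) -> np.ndarray:
    """Draw an event ordering uniformly from the valid orderings.

    A uniform permutation is drawn and the positions occupied by each
    biomarker's events are refilled with those events in ascending z order;
    every valid ordering has the same number of permutation preimages, so
    the result is uniform over valid orderings.
    """
    perm = rng.permutation(event_set.S)
    out = np.empty_like(perm)
    for b in range(event_set.n_biomarkers):
        evs = np.flatnonzero(event_set.event_biomarker_idx == b)
        slots = np.sort(np.flatnonzero(np.isin(perm, evs)))
        out[slots] = evs
    return out


def sequence_kendall_tau(a: Sequence[int], b: Sequence[int]) -> float:
    """Kendall rank correlation between two event orderings.

    Computed between the per-event position vectors of the two sequences;
    1.0 means identical orderings, -1.0 a full reversal.
    """
    from scipy.stats import kendalltau

    a = np.asarray(a, dtype=np.intp)
    b = np.asarray(b, dtype=np.intp)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    S = a.size
    pos_a = np.empty(S, dtype=np.intp)
    pos_b = np.empty(S, dtype=np.intp)
    pos_a[a] = np.arange(S)
    pos_b[b] = np.arange(S)
    tau = kendalltau(pos_a, pos_b).statistic
    return float(tau)
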