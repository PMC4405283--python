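"""Risk sets and history statistics for the conditional-logit event model.

Every modelled onset becomes one *stratum*: the realized event together with
the alternative onsets that could have happened at the same instant.  A pair
onset (from the empty state) competes with the other two dyads, so its
stratum has three rows; a group onset (from a one-tie state) competes only
with the other way the unconnected animal could have joined, so its stratum
has two rows.

Each row carries five history statistics for its candidate dyad:

* ``unfam``      — 1 if the candidate tie involves the unfamiliar animal (3);
* ``pair_hour``  — this dyad's pair onsets in the trailing hour;
* ``pair_day``   — this dyad's pair onsets since the start of the day;
* ``group_hour`` — group onsets in the trailing hour whose resulting
  configuration included this dyad as one of its two ties;
* ``group_day``  — the same count since the start of the day.

Windows never reach into the previous day: the hour window is open at its
lower end, ``(t − 3600, t)``, and both windows are truncated at the day
start, so an event aged exactly one hour has just expired and hourly counts
are nested within daily counts.  Count statistics are z-scaled per fitted
dataset; the binary ``unfam`` indicator is left on its natural scale.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .events import Event, EventStream, StateError
from .logger_io import DYADS

#: Statistic (effect) names, in column order.
STAT_NAMES = ("unfam", "pair_hour", "pair_day", "group_hour", "group_day")

MODEL_TYPES = ("pair", "group")


@dataclass(frozen=True)
class Stratum:
    """One modelled onset with its risk set.

    ``outcome[i]`` is 1 for the realized candidate (exactly one per stratum)
    and ``stats[i]`` is the statistics vector of candidate ``dyads[i]``.
    """

    stratum_id: str
    triad_id: str
    model_type: str
    day: int
    t: int
    dyads: tuple[tuple[int, int], ...]
    outcome: np.ndarray
    stats: np.ndarray

    def __post_init__(self) -> None:
        k = {"pair": 3, "group": 2}[self.model_type]
        if len(self.dyads) != k or self.stats.shape[0] != k:
            raise ValueError(
                f"{self.model_type} stratum must have {k} rows, got {len(self.dyads)}"
            )
        if int(np.sum(self.outcome)) != 1:
            raise ValueError("stratum must have exactly one realized outcome")


def candidate_dyads(
    active_ties: frozenset | set, model_type: str
) -> tuple[tuple[int, int], ...]:
    """The onsets possible from ``active_ties`` under the given model."""
    if model_type == "pair":
        if active_ties:
            raise StateError("pair onsets require the empty state")
        return DYADS
    if model_type == "group":
        if len(active_ties) != 1:
            raise StateError("group onsets require exactly one active tie")
        (tie,) = active_ties
        lone = ({1, 2, 3} - set(tie)).pop()
        return tuple(
            sorted((min(a, lone), max(a, lone)) for a in tie)
        )
    raise ValueError(f"unknown model type {model_type!r}")


def enumerate_risk_set(
    active_ties: frozenset | set,
    realized_dyad: tuple[int, int],
    model_type: str,
) -> tuple[tuple[int, int], ...]:
    """Candidates for a realized onset; validates that it is among them."""
    cands = candidate_dyads(active_ties, model_type)
    if realized_dyad not in cands:
        raise StateError(
            f"realized dyad {realized_dyad} not a candidate from {set(active_ties)}"
        )
    return cands


def compute_statistics(
    history: Iterable[Event],
    dyad: tuple[int, int],
    t: int,
    day_start: int = 0,
    hour_window_s: int = 3600,
) -> np.ndarray:
    """History statistics for ``dyad`` at time ``t`` by direct scan.

    Counts onsets with event time in ``[day_start, t)`` (daily) and
    additionally strictly within the trailing ``hour_window_s`` (hourly).
    Offsets and triangle onsets never contribute.
    """
    unfam = 1.0 if 3 in dyad else 0.0
    pair_hour = pair_day = group_hour = group_day = 0
    hour_lo = t - hour_window_s  # exclusive
    for e in history:
        if e.kind != "onset" or e.t < day_start or e.t >= t:
            continue
        if e.etype == "pair" and e.dyad == dyad:
            pair_day += 1
            if e.t > hour_lo:
                pair_hour += 1
        elif e.etype == "group" and dyad in e.ties_after:
            group_day += 1
            if e.t > hour_lo:
                group_hour += 1
    return np.array([unfam, pair_hour, pair_day, group_hour, group_day])


class _Counters:
    """Incremental windowed counts, equivalent to :func:`compute_statistics`
    but O(1) amortised per query.  Reset at every day boundary."""

    __slots__ = ("hour_window_s", "pair_day", "group_day", "pair_hq", "group_hq")

    def __init__(self, hour_window_s: int) -> None:
        self.hour_window_s = hour_window_s
        self.reset()

    def reset(self) -> None:
        self.pair_day = {d: 0 for d in DYADS}
        self.group_day = {d: 0 for d in DYADS}
        self.pair_hq = {d: deque() for d in DYADS}
        self.group_hq = {d: deque() for d in DYADS}

    def expire(self, t: int) -> None:
        cut = t - self.hour_window_s  # events at exactly the cut have expired
        for qs in (self.pair_hq, self.group_hq):
            for q in qs.values():
                while q and q[0] <= cut:
                    q.popleft()

    def query(self, dyad: tuple[int, int]) -> np.ndarray:
        return np.array(
            [
                1.0 if 3 in dyad else 0.0,
                len(self.pair_hq[dyad]),
                self.pair_day[dyad],
                len(self.group_hq[dyad]),
                self.group_day[dyad],
            ]
        )

    def record(self, e: Event) -> None:
        if e.kind != "onset":
            return
        if e.etype == "pair":
            self.pair_day[e.dyad] += 1
            self.pair_hq[e.dyad].append(e.t)
        elif e.etype == "group":
            for d in e.ties_after:
                self.group_day[d] += 1
                self.group_hq[d].append(e.t)

    def next_expiry(self, after: float) -> float:
        nxt = float("inf")
        for qs in (self.pair_hq, self.group_hq):
            for q in qs.values():
                if q:
                    cand = q[0] + self.hour_window_s
                    if cand > after:
                        nxt = min(nxt, cand)
        return nxt


def build_strata(
    stream: EventStream,
    model_type: str,
    day: int | None = None,
    hour_window_s: int = 3600,
) -> list[Stratum]:
    """One stratum per onset of ``model_type`` (optionally restricted to one
    day), with statistics computed against this triad's own prior history.

    Day 1 starts at introduction (time zero), so on the introduction day the
    daily statistics cover everything that has happened at all.  Triangle
    onsets yield no strata.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    counters = _Counters(hour_window_s)
    strata: list[Stratum] = []
    cur_day: int | None = None
    for e in stream:
        if cur_day is None or e.day > cur_day:
            counters.reset()
            cur_day = e.day
        if (
            e.kind == "onset"
            and e.etype == model_type
            and (day is None or e.day == day)
        ):
            counters.expire(e.t)
            pre_state = e.ties_after - {e.dyad}
            cands = enumerate_risk_set(pre_state, e.dyad, model_type)
            stats = np.vstack([counters.query(c) for c in cands])
            outcome = np.array([1 if c == e.dyad else 0 for c in cands])
            strata.append(
                Stratum(
                    stratum_id=f"{stream.triad_id}:d{e.day}:{model_type}:{e.t}",
                    triad_id=stream.triad_id,
                    model_type=model_type,
                    day=e.day,
                    t=e.t,
                    dyads=cands,
                    outcome=outcome,
                    stats=stats,
                )
            )
        counters.record(e)
    return strata


class Normalization(NamedTuple):
    """Column centring/scale actually applied to the count statistics."""

    mean: np.ndarray  # length 4, columns 2-5
    sd: np.ndarray  # length 4; 0 marks a constant (zeroed-out) column


def normalize_statistics(
    strata: Sequence[Stratum], return_scales: bool = False
):
    """Z-scale the four count columns across all rows of one fitted dataset.

    Centring is cosmetic under a conditional likelihood (per-dataset shifts
    cancel within strata); the division by the sample standard deviation puts
    effects on comparable scales.  Zero-variance columns become all zeros and
    the ``unfam`` indicator is never rescaled.
    """
    if not strata:
        norm = Normalization(np.zeros(4), np.zeros(4))
        return ([], norm) if return_scales else []
    X = np.vstack([s.stats for s in strata])
    counts = X[:, 1:]
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(4)
    safe = np.where(sd > 0, sd, 1.0)
    out = []
    for s in strata:
        stats = s.stats.copy()
        stats[:, 1:] = (stats[:, 1:] - mean) / safe
        stats[:, 1:][:, sd == 0] = 0.0
        out.append(replace(s, stats=stats))
    norm = Normalization(mean=mean, sd=sd)
    return (out, norm) if return_scales else out


def strata_to_frame(strata: Sequence[Stratum]) -> pd.DataFrame:
    """Long-format design table (one row per candidate event)."""
    rows = []
    for s in strata:
        for i, d in enumerate(s.dyads):
            rec = {
                "stratum_id": s.stratum_id,
                "triad_id": s.triad_id,
                "model_type": s.model_type,
                "day": s.day,
                "t": s.t,
                "dyad": f"{d[0]}-{d[1]}",
                "outcome": int(s.outcome[i]),
            }
            rec.update({name: s.stats[i, j] for j, name in enumerate(STAT_NAMES)})
            rows.append(rec)
    return pd.DataFrame(
        rows,
        columns=["stratum_id", "triad_id", "model_type", "day", "t", "dyad", "outcome"]
        + list(STAT_NAMES),
    )


def strata_from_frame(df: pd.DataFrame) -> list[Stratum]:
    strata = []
    for sid, g in df.groupby("stratum_id", sort=False):
        dyads = tuple(
            (int(s.split("-")[0]), int(s.split("-")[1])) for s in g["dyad"]
        )
        strata.append(
            Stratum(
                stratum_id=str(sid),
                triad_id=str(g["triad_id"].iloc[0]),
                model_type=str(g["model_type"].iloc[0]),
                day=int(g["day"].iloc[0]),
                t=int(g["t"].iloc[0]),
                dyads=dyads,
                outcome=g["outcome"].to_numpy(),
                stats=g[list(STAT_NAMES)].to_numpy(dtype=float),
            )
        )
    return strata


def pool_strata(
    streams: Iterable[EventStream],
    model_type: str,
    day: int | None = None,
    hour_window_s: int = 3600,
) -> list[Stratum]:
    """Concatenate per-triad strata into one dataset (histories stay
    triad-local; only the likelihood is pooled)."""
    out: list[Stratum] = []
    for stream in streams:
        out.extend(build_strata(stream, model_type, day=day, hour_window_s=hour_window_s))
    return out
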