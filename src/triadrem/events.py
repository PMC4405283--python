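"""Classified onset/offset event streams over the state of a triad.

A triad is described at any instant by which of its three dyads are in
contact.  Every contact interval contributes two events: an *onset* when the
tie appears and an *offset* when it dissolves.  Onsets are classified by the
configuration just before they happen:

* ``pair`` — from the empty state, an isolated dyad forms;
* ``group`` — one tie already exists and the third animal joins one of its
  members, so all three animals are now involved;
* ``triangle`` — two ties already exist and the onset closes the last open
  dyad.  From a two-tie state this is the only possible onset, so triangles
  carry no choice information and are never modelled, only counted.

Offsets are classified symmetrically by how many ties exist when they occur
(``pair_dissolution`` / ``group_dissolution`` / ``triangle_dissolution``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .logger_io import DYADS, ContactInterval

SECONDS_PER_DAY = 86400

ONSET_TYPES = ("pair", "group", "triangle")
OFFSET_TYPES = ("pair_dissolution", "group_dissolution", "triangle_dissolution")


class StateError(ValueError):
    """An event is inconsistent with the triad state it arrives in."""


@dataclass(frozen=True)
class DayGrid:
    """Assigns day indices to triad-clock times.

    ``calendar`` mode (default) follows the local calendar: day 1 is the
    (usually partial) calendar day containing the introduction, which sits
    ``intro_offset_s`` seconds after that day's midnight.  ``fixed`` mode uses
    24 h blocks counted from the introduction itself.
    """

    mode: str = "calendar"
    intro_offset_s: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("calendar", "fixed"):
            raise ValueError(f"unknown day boundary mode {self.mode!r}")
        if not 0 <= self.intro_offset_s < SECONDS_PER_DAY:
            raise ValueError("intro_offset_s must lie within one day")

    def day_index(self, t: int) -> int:
        if self.mode == "fixed":
            return int(t) // SECONDS_PER_DAY + 1
        return (int(t) + self.intro_offset_s) // SECONDS_PER_DAY + 1

    def day_start(self, day: int) -> int:
        """First second (triad clock) of ``day``; clipped at 0 for day 1."""
        if self.mode == "fixed":
            return (day - 1) * SECONDS_PER_DAY
        return max(0, (day - 1) * SECONDS_PER_DAY - self.intro_offset_s)


@dataclass(frozen=True, slots=True)
class Event:
    """One onset or offset, with its classification and day index.

    ``ties_after`` is the set of active dyads immediately after the event;
    for a group onset it is exactly the two ties of the configuration the
    event produced, which is what the group history statistics credit.
    """

    t: int
    dyad: tuple[int, int]
    kind: str  # "onset" | "offset"
    etype: str
    day: int
    ties_after: frozenset


def classify_onset(active_ties: frozenset | set, dyad: tuple[int, int]) -> str:
    """Classify an onset of ``dyad`` against the current set of active ties."""
    if dyad in active_ties:
        raise StateError(f"onset of already-active dyad {dyad}")
    n = len(active_ties)
    if n == 0:
        return "pair"
    if n == 1:
        return "group"
    return "triangle"


def classify_offset(active_ties: frozenset | set, dyad: tuple[int, int]) -> str:
    """Classify an offset of ``dyad`` by the configuration it dissolves."""
    if dyad not in active_ties:
        raise StateError(f"offset of inactive dyad {dyad}")
    n = len(active_ties)
    if n == 3:
        return "triangle_dissolution"
    if n == 2:
        return "group_dissolution"
    return "pair_dissolution"


class EventStream:
    """A time-ordered sequence of classified events for one triad."""

    def __init__(
        self,
        events: Sequence[Event],
        grid: DayGrid | None = None,
        triad_id: str = "triad",
    ) -> None:
        self.events = list(events)
        self.grid = grid if grid is not None else DayGrid()
        self.triad_id = triad_id

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self) -> list[Event]:
        return [e for e in self.events if e.kind == "onset"]

    def days(self) -> list[int]:
        return sorted({e.day for e in self.events})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "triad_id": self.triad_id,
                "t": e.t,
                "dyad": f"{e.dyad[0]}-{e.dyad[1]}",
                "kind": e.kind,
                "etype": e.etype,
                "day": e.day,
                "ties_after": ";".join(
                    f"{a}-{b}" for a, b in sorted(e.ties_after)
                ),
            }
            for e in self.events
        ]
        return pd.DataFrame(
            rows,
            columns=["triad_id", "t", "dyad", "kind", "etype", "day", "ties_after"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, grid: DayGrid | None = None) -> "EventStream":
        def _dyad(s: str) -> tuple[int, int]:
            a, b = s.split("-")
            return (int(a), int(b))

        events = []
        triad_id = "triad"
        for row in df.itertuples(index=False):
            triad_id = str(row.triad_id)
            ties = row.ties_after
            ties_after = frozenset(
                _dyad(p) for p in str(ties).split(";") if p and p != "nan"
            ) if isinstance(ties, str) and ties else frozenset()
            events.append(
                Event(
                    int(row.t), _dyad(row.dyad), row.kind, row.etype,
                    int(row.day), ties_after,
                )
            )
        return cls(events, grid=grid, triad_id=triad_id)


def build_event_stream(
    intervals: Mapping[tuple[int, int], Sequence[ContactInterval]]
    | Iterable[ContactInterval],
    grid: DayGrid | None = None,
    triad_id: str = "triad",
) -> EventStream:
    """Merge per-dyad intervals into one classified, time-ordered stream.

    At equal seconds, offsets are processed before onsets so a dissolving tie
    never inflates the configuration seen by a new onset; coinciding events of
    the same kind are ordered by dyad code.  Onset seconds are expected to be
    already unique (see :func:`triadrem.logger_io.break_onset_ties`).
    """
    if grid is None:
        grid = DayGrid()
    if isinstance(intervals, Mapping):
        flat: list[ContactInterval] = [iv for ivs in intervals.values() for iv in ivs]
    else:
        flat = list(intervals)
    raw: list[tuple[int, int, tuple[int, int], str]] = []
    for iv in flat:
        raw.append((iv.onset_t, 1, iv.dyad, "onset"))
        raw.append((iv.offset_t, 0, iv.dyad, "offset"))
    raw.sort()
    active: set[tuple[int, int]] = set()
    events: list[Event] = []
    for t, _, dyad, kind in raw:
        try:
            if kind == "onset":
                etype = classify_onset(active, dyad)
                active.add(dyad)
            else:
                etype = classify_offset(active, dyad)
                active.discard(dyad)
        except StateError as exc:
            raise StateError(f"t={t}: {exc}") from exc
        events.append(Event(t, dyad, kind, etype, grid.day_index(t), frozenset(active)))
    return EventStream(events, grid=grid, triad_id=triad_id)


def summarize_event_counts(stream: EventStream | Iterable[Event]) -> pd.DataFrame:
    """Per-day counts of each onset and offset type, with totals.

    One row per day; onset columns (pair, group, triangle, total_onsets) and
    dissolution columns (pair_dissolution, group_dissolution,
    triangle_dissolution, total_offsets).
    """
    events = stream.events if isinstance(stream, EventStream) else list(stream)
    cols = list(ONSET_TYPES) + list(OFFSET_TYPES)
    counts: dict[int, dict[str, int]] = {}
    for e in events:
        row = counts.setdefault(e.day, {c: 0 for c in cols})
        row[e.etype] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").sort_index()
    if df.empty:
        df = pd.DataFrame(columns=cols, dtype=int)
    df = df.reindex(columns=cols, fill_value=0)
    df["total_onsets"] = df[list(ONSET_TYPES)].sum(axis=1)
    df["total_offsets"] = df[list(OFFSET_TYPES)].sum(axis=1)
    df.index.name = "day"
    return df
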