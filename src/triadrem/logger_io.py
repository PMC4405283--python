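"""Reading, validation and canonicalisation of proximity-logger contact streams.

Collar-mounted proximity loggers record one row per close-proximity encounter:
the focal animal, the animal it met, start and end timestamps (1 s resolution)
and the duration in whole seconds.  Both collars of a dyad may log the same
encounter with slightly different boundaries, so raw streams have to be merged
("reciprocal compression") before they can be treated as a single set of
contact intervals per dyad.

This module parses that dialect, applies the minimum-duration filter used to
suppress edge-of-range detections, expresses everything in seconds since the
moment the unfamiliar animal was introduced to the resident pair, merges
reciprocal reports into maximal disjoint intervals, and de-duplicates
coinciding onset seconds so that downstream event ordering is unambiguous.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import yaml

#: The three unordered dyads of a triad, by animal code (3 = unfamiliar).
DYADS: tuple[tuple[int, int], ...] = ((1, 2), (1, 3), (2, 3))

LOGGER_HEADER = [
    "Cow ID",
    "Encountered cow ID",
    "Start date",
    "Start time",
    "End date",
    "End time",
    "Duration (seconds)",
]


class LoggerParseError(ValueError):
    """A row of the logger stream could not be parsed at all."""


class LoggerValidationError(ValueError):
    """A row parsed but violates an internal consistency rule."""


@dataclass(frozen=True)
class ContactRecord:
    """One raw logger row: a single reported close-proximity encounter."""

    focal_id: str
    partner_id: str
    start: datetime
    end: datetime
    duration_s: int

    def __post_init__(self) -> None:
        if self.focal_id == self.partner_id:
            raise LoggerValidationError(
                f"focal and partner are the same animal: {self.focal_id!r}"
            )
        if self.end < self.start:
            raise LoggerValidationError(
                f"end {self.end} precedes start {self.start}"
            )
        span = int((self.end - self.start).total_seconds())
        if span != self.duration_s:
            raise LoggerValidationError(
                f"duration column {self.duration_s} disagrees with "
                f"timestamp span {span}"
            )


@dataclass(frozen=True)
class ContactInterval:
    """A cleaned per-dyad contact, half-open [onset_t, offset_t) in seconds
    since introduction."""

    dyad: tuple[int, int]
    onset_t: int
    offset_t: int

    def __post_init__(self) -> None:
        if self.dyad not in DYADS:
            raise ValueError(f"not a triad dyad: {self.dyad}")
        if self.onset_t < 0:
            raise ValueError(f"onset before introduction: {self.onset_t}")
        if self.offset_t <= self.onset_t:
            raise ValueError(
                f"empty interval [{self.onset_t}, {self.offset_t})"
            )


@dataclass(frozen=True)
class TriadManifest:
    """Maps raw logger animal IDs to triad codes 1, 2 (residents) and
    3 (the newly introduced, unfamiliar animal), and fixes time zero."""

    triad_id: str
    id_map: Mapping[str, int]
    introduction: datetime

    def __post_init__(self) -> None:
        codes = sorted(self.id_map.values())
        if codes != [1, 2, 3]:
            raise ValueError(
                f"manifest must assign codes 1,2,3 to exactly three animals, "
                f"got {codes}"
            )

    def code_of(self, raw_id: str) -> int:
        return self.id_map[raw_id]

    def raw_of(self, code: int) -> str:
        for raw, c in self.id_map.items():
            if c == code:
                return raw
        raise KeyError(code)


@dataclass
class ParseReport:
    """Row accounting from one parse: totals and rejected rows."""

    n_rows: int = 0
    n_parsed: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)


def _parse_timestamp(date_s: str, time_s: str, row: int, dayfirst: bool) -> datetime:
    date_s, time_s = date_s.strip(), time_s.strip()
    fmts = ["%d/%m/%Y", "%Y-%m-%d"] if dayfirst else ["%m/%d/%Y", "%Y-%m-%d"]
    for fmt in fmts:
        try:
            return datetime.strptime(f"{date_s} {time_s}", f"{fmt} %H:%M:%S")
        except ValueError:
            continue
    raise LoggerParseError(
        f"row {row}: malformed timestamp {date_s!r} {time_s!r}"
    )


def _as_text(source: str | Path | TextIO) -> str:
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    if not source or "\n" in source or "," in source or "\t" in source:
        return source
    return Path(source).read_text()


def parse_logger_file(
    source: str | Path | TextIO,
    manifest: TriadManifest,
    *,
    dayfirst: bool = True,
    report: ParseReport | None = None,
) -> list[ContactRecord]:
    """Parse a delimited logger stream into :class:`ContactRecord` rows.

    The delimiter (comma or tab) is auto-detected from the header line.
    The printed duration column is cross-checked against the timestamp span
    and a :class:`LoggerValidationError` names the offending row on any
    disagreement.  Rows mentioning animals outside the manifest are not
    errors: they are skipped and listed in ``report.rejected``.
    """
    text = _as_text(source)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    delim = "\t" if "\t" in lines[0] else ","
    rows = list(csv.reader(io.StringIO("\n".join(lines)), delimiter=delim))
    header, body = rows[0], rows[1:]
    if len(header) != len(LOGGER_HEADER):
        raise LoggerParseError(
            f"expected {len(LOGGER_HEADER)} columns, header has {len(header)}"
        )
    if report is None:
        report = ParseReport()
    records: list[ContactRecord] = []
    for i, row in enumerate(body, start=2):  # 1-based, after header
        report.n_rows += 1
        if len(row) != len(LOGGER_HEADER):
            raise LoggerParseError(f"row {i}: expected 7 fields, got {len(row)}")
        focal, partner, sd, st, ed, et, dur_s = (f.strip() for f in row)
        if focal not in manifest.id_map or partner not in manifest.id_map:
            report.rejected.append((i, f"unknown animal(s) {focal!r}/{partner!r}"))
            continue
        start = _parse_timestamp(sd, st, i, dayfirst)
        end = _parse_timestamp(ed, et, i, dayfirst)
        try:
            dur = int(dur_s)
        except ValueError as exc:
            raise LoggerParseError(f"row {i}: bad duration {dur_s!r}") from exc
        try:
            rec = ContactRecord(focal, partner, start, end, dur)
        except LoggerValidationError as exc:
            raise LoggerValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
        report.n_parsed += 1
    return records


def filter_short_contacts(
    records: Sequence[ContactRecord], min_duration_s: int = 2
) -> list[ContactRecord]:
    """Drop contacts shorter than ``min_duration_s`` (edge-of-range noise);
    a contact of exactly the minimum length is retained."""
    return [r for r in records if r.duration_s >= min_duration_s]


def compress_reciprocal(
    records: Iterable[ContactRecord], manifest: TriadManifest
) -> dict[tuple[int, int], list[ContactInterval]]:
    """Merge reciprocal logger reports into maximal disjoint intervals.

    Each record is re-expressed on the triad clock (seconds since
    introduction); records ending at or before introduction are dropped and
    records straddling it are clipped to start at 0.  Per dyad, the union of
    all reported spans is taken, with overlapping or abutting spans merged,
    which is the most permissive reading of a contact: the dyad is in contact
    during every second at least one collar says so.
    """
    intro = manifest.introduction
    spans: dict[tuple[int, int], list[tuple[int, int]]] = {d: [] for d in DYADS}
    for r in records:
        a = manifest.code_of(r.focal_id)
        b = manifest.code_of(r.partner_id)
        dyad = (min(a, b), max(a, b))
        s = int((r.start - intro).total_seconds())
        e = s + r.duration_s
        if e <= 0:
            continue
        s = max(s, 0)
        if e <= s:
            continue
        spans[dyad].append((s, e))
    out: dict[tuple[int, int], list[ContactInterval]] = {}
    for dyad in DYADS:
        merged: list[list[int]] = []
        for s, e in sorted(spans[dyad]):
            if merged and s <= merged[-1][1]:  # overlap or abut
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[dyad] = [ContactInterval(dyad, s, e) for s, e in merged]
    return out


def _flatten(
    intervals: Mapping[tuple[int, int], Sequence[ContactInterval]]
    | Iterable[ContactInterval],
) -> list[ContactInterval]:
    if isinstance(intervals, Mapping):
        flat: list[ContactInterval] = []
        for ivs in intervals.values():
            flat.extend(ivs)
        return flat
    return list(intervals)


def break_onset_ties(
    intervals: Mapping[tuple[int, int], Sequence[ContactInterval]]
    | Iterable[ContactInterval],
) -> dict[tuple[int, int], list[ContactInterval]]:
    """Make every onset second globally unique.

    Coinciding onsets are ordered by dyad code ((1,2) < (1,3) < (2,3)) and the
    2nd..k-th shifted forward by +1..+(k−1) s, cascading past any second that
    is already taken.  An offset moves with its onset only if the shift would
    otherwise leave an empty interval.  Processing in (onset, dyad) order makes
    assigned onsets strictly increasing, so the result is deterministic and
    per-dyad onset order is preserved.
    """
    flat = sorted(_flatten(intervals), key=lambda iv: (iv.onset_t, iv.dyad))
    used: set[int] = set()
    out: dict[tuple[int, int], list[ContactInterval]] = {d: [] for d in DYADS}
    for iv in flat:
        t = iv.onset_t
        while t in used:
            t += 1
        off = iv.offset_t if iv.offset_t > t else iv.offset_t + (t - iv.onset_t)
        used.add(t)
        out[iv.dyad].append(ContactInterval(iv.dyad, t, off))
    return out


# ---------------------------------------------------------------------------
# text round-trips: manifests, interval files, and the logger dialect itself
# ---------------------------------------------------------------------------

def read_manifest(source: str | Path | TextIO, *, dayfirst: bool = True) -> TriadManifest:
    text = _as_text(source) if not isinstance(source, (str, Path)) else None
    if text is None:
        text = Path(source).read_text()
    doc = yaml.safe_load(text)
    intro = doc["introduction"]
    if isinstance(intro, str):
        intro = _parse_timestamp(*intro.split(" ", 1), row=0, dayfirst=dayfirst)
    return TriadManifest(
        triad_id=str(doc["triad_id"]),
        id_map={str(k): int(v) for k, v in doc["animals"].items()},
        introduction=intro,
    )


def write_manifest(manifest: TriadManifest, path: str | Path) -> None:
    doc = {
        "triad_id": manifest.triad_id,
        "introduction": manifest.introduction.strftime("%d/%m/%Y %H:%M:%S"),
        "animals": dict(manifest.id_map),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def intervals_to_records(
    intervals: Mapping[tuple[int, int], Sequence[ContactInterval]]
    | Iterable[ContactInterval],
    manifest: TriadManifest,
) -> list[ContactRecord]:
    """Express canonical intervals back in the raw logger dialect (one record
    per interval, reported by the lower-coded animal's collar)."""
    recs = []
    for iv in sorted(_flatten(intervals), key=lambda iv: (iv.onset_t, iv.dyad)):
        start = manifest.introduction + timedelta(seconds=iv.onset_t)
        end = manifest.introduction + timedelta(seconds=iv.offset_t)
        recs.append(
            ContactRecord(
                focal_id=manifest.raw_of(iv.dyad[0]),
                partner_id=manifest.raw_of(iv.dyad[1]),
                start=start,
                end=end,
                duration_s=iv.offset_t - iv.onset_t,
            )
        )
    return recs


def write_logger_text(records: Iterable[ContactRecord], *, delimiter: str = ",") -> str:
    """Serialise records in the logger dialect (day-first dates)."""
    buf = io.StringIO()
    w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    w.writerow(LOGGER_HEADER)
    for r in records:
        w.writerow(
            [
                r.focal_id,
                r.partner_id,
                r.start.strftime("%d/%m/%Y"),
                r.start.strftime("%H:%M:%S"),
                r.end.strftime("%d/%m/%Y"),
                r.end.strftime("%H:%M:%S"),
                r.duration_s,
            ]
        )
    return buf.getvalue()


def write_intervals(
    intervals: Mapping[tuple[int, int], Sequence[ContactInterval]]
    | Iterable[ContactInterval],
    triad_id: str,
    path_or_buf: str | Path | TextIO,
) -> None:
    lines = ["triad_id\tdyad\tonset_t\toffset_t"]
    for iv in sorted(_flatten(intervals), key=lambda iv: (iv.onset_t, iv.dyad)):
        lines.append(f"{triad_id}\t{iv.dyad[0]}-{iv.dyad[1]}\t{iv.onset_t}\t{iv.offset_t}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        Path(path_or_buf).write_text(text)


def read_intervals(
    source: str | Path | TextIO,
) -> dict[tuple[int, int], list[ContactInterval]]:
    text = _as_text(source)
    out: dict[tuple[int, int], list[ContactInterval]] = {d: [] for d in DYADS}
    for ln in text.splitlines()[1:]:
        if not ln.strip():
            continue
        _, dyad_s, s, e = ln.split("\t")
        a, b = dyad_s.split("-")
        out[(int(a), int(b))].append(
            ContactInterval((int(a), int(b)), int(s), int(e))
        )
    return out
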