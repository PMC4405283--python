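"""Generative simulator for triad proximity studies.

Simulates the contact process of one triad in continuous time: from the
empty state each of the three dyads starts a pair contact at rate
exp(beta0_pair + theta_pair·s), from a one-tie state the two ways of joining
the unconnected animal occur at rate exp(beta0_group + theta_group·s), and
from a two-tie state the closing (triangle) onset occurs at the bare group
baseline — triangles are generated but never modelled, exactly as in the
fitting pipeline.  Active ties dissolve independently at a constant hazard.

The statistics s are the unnormalised history statistics of
:mod:`triadrem.design`, recomputed from the realized history with the same
day resets and hour-window expiries, so rates are piecewise constant between
event times, window expiries and day boundaries; sampling uses competing
exponentials with re-sampling at every rate breakpoint.

Event times are recorded on the integer-second logger clock, strictly
increasing, and every contact lasts at least the minimum duration the
ingestion filter keeps, so re-ingesting the emitted logger records through
:mod:`triadrem.logger_io` and :mod:`triadrem.events` reproduces the true
event stream exactly — the round-trip contract the tests lean on.
A baseline log-rate exists only here: the conditional likelihood is
invariant to it, which parameter-recovery tests exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

from . import logger_io
from .design import _Counters, candidate_dyads
from .events import DayGrid, Event, EventStream
from .logger_io import DYADS, ContactInterval, ContactRecord, TriadManifest


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic triad study.

    Defaults emulate the scale of the motivating cattle experiment: 36
    triads, a mid-day introduction followed by five calendar days of
    monitoring, a few dozen onsets per triad-day with familiar dyads
    favoured for pair events and the unfamiliar animal over-represented in
    group formation, and mean contact bouts of ~100 s.
    """

    beta0_pair: float = -8.7  # log pair-onset rate per dyad per second
    beta0_group: float = -6.9  # log group/triangle-onset rate per candidate
    theta_pair: tuple[float, ...] = (-0.5, 0.05, 0.02, 0.03, 0.01)
    theta_group: tuple[float, ...] = (0.5, -0.05, 0.02, 0.04, 0.01)
    offset_hazard: float = 0.01  # per-tie dissolution rate (1/s)
    horizon_days: int = 5
    introduction: datetime = datetime(2009, 3, 9, 12, 0, 0)
    day_boundary_mode: str = "calendar"
    hour_window_s: int = 3600
    min_interval_s: int = 2
    reciprocal_noise: bool = False
    n_triads: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.offset_hazard <= 0:
            raise ValueError("offset_hazard must be positive")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be at least 1")

    @property
    def intro_offset_s(self) -> int:
        t = self.introduction
        return t.hour * 3600 + t.minute * 60 + t.second

    def grid(self) -> DayGrid:
        offset = self.intro_offset_s if self.day_boundary_mode == "calendar" else 0
        return DayGrid(self.day_boundary_mode, offset)


@dataclass(frozen=True)
class Decision:
    """One modelled onset as the generator saw it: the candidates, the
    unnormalised statistics the rates used, and the realized dyad."""

    t: int
    model_type: str
    dyads: tuple[tuple[int, int], ...]
    stats: np.ndarray
    chosen: tuple[int, int]


@dataclass
class TriadSim:
    """Ground truth for one simulated triad."""

    triad_id: str
    manifest: TriadManifest
    records: list[ContactRecord]
    intervals: list[ContactInterval]
    stream: EventStream
    decisions: list[Decision] | None
    config: SimConfig


@dataclass
class Study:
    """A collection of independent simulated triads plus their parameters."""

    config: SimConfig
    sims: list[TriadSim]

    @property
    def streams(self) -> list[EventStream]:
        return [s.stream for s in self.sims]

    def write(self, outdir: str | Path) -> None:
        """Emit logger-dialect contact files and manifests per triad, plus
        the true event streams and generative parameters for tests."""
        outdir = Path(outdir)
        (outdir / "triads").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        for sim in self.sims:
            (outdir / "triads" / f"{sim.triad_id}.contacts.csv").write_text(
                logger_io.write_logger_text(sim.records)
            )
            logger_io.write_manifest(
                sim.manifest, outdir / "triads" / f"{sim.triad_id}.manifest.yaml"
            )
            sim.stream.to_frame().to_csv(
                outdir / "truth" / f"{sim.triad_id}.events.tsv", sep="\t", index=False
            )
        import json

        params = {
            "beta0_pair": self.config.beta0_pair,
            "beta0_group": self.config.beta0_group,
            "theta_pair": list(self.config.theta_pair),
            "theta_group": list(self.config.theta_group),
            "offset_hazard": self.config.offset_hazard,
            "horizon_days": self.config.horizon_days,
            "introduction": self.config.introduction.isoformat(),
            "n_triads": self.config.n_triads,
            "seed": self.config.seed,
        }
        (outdir / "truth" / "params.json").write_text(json.dumps(params, indent=2))


def _onset_rates(
    cfg: SimConfig,
    ties: set,
    counters: _Counters,
) -> tuple[str | None, tuple[tuple[int, int], ...], np.ndarray, np.ndarray]:
    """(model type, candidate dyads, stats matrix, rates) for the current state."""
    n = len(ties)
    if n == 0:
        model = "pair"
        beta0, theta = cfg.beta0_pair, np.asarray(cfg.theta_pair)
        cands = candidate_dyads(ties, "pair")
    elif n == 1:
        model = "group"
        beta0, theta = cfg.beta0_group, np.asarray(cfg.theta_group)
        cands = candidate_dyads(ties, "group")
    elif n == 2:
        missing = tuple(d for d in DYADS if d not in ties)
        return "triangle", missing, np.zeros((1, 5)), np.array(
            [math.exp(cfg.beta0_group)]
        )
    else:
        return None, (), np.zeros((0, 5)), np.zeros(0)
    stats = np.vstack([counters.query(c) for c in cands])
    eta = beta0 + stats @ theta
    if np.any(np.abs(eta) > 30):
        raise SimulationError(
            "onset log-rate exceeded +/-30; use smaller baseline or theta"
        )
    return model, cands, stats, np.exp(eta)


def simulate_triad(
    config: SimConfig,
    seed: int | np.random.Generator,
    triad_id: str = "T01",
    log_decisions: bool = False,
) -> TriadSim:
    """Simulate one triad and package it as logger records plus ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = config.grid()
    t_end = grid.day_start(config.horizon_days + 1)
    counters = _Counters(config.hour_window_s)
    ties: set[tuple[int, int]] = set()
    onset_at: dict[tuple[int, int], int] = {}
    events: list[Event] = []
    intervals: list[ContactInterval] = []
    decisions: list[Decision] | None = [] if log_decisions else None
    last_t = -1
    cur_day = 1
    day_end = grid.day_start(2)
    t = 0.0

    def roll_day_to(time: float) -> None:
        nonlocal cur_day, day_end
        while time >= day_end and cur_day <= config.horizon_days:
            cur_day += 1
            day_end = grid.day_start(cur_day + 1)
            counters.reset()

    while True:
        counters.expire(t)
        model, cands, stats, rates = _onset_rates(config, ties, counters)
        off_rate = config.offset_hazard * len(ties)
        total = float(rates.sum()) + off_rate
        breakpoint_t = min(float(day_end), counters.next_expiry(t))
        if total <= 0.0:
            t = breakpoint_t
        else:
            wait = rng.exponential() / total
            if t + wait >= breakpoint_t:
                t = breakpoint_t
            else:
                tau = t + wait
                ti = int(tau)
                if ti <= last_t:
                    ti = last_t + 1
                if ti >= t_end:
                    break
                u = rng.random() * total
                acc = 0.0
                chosen_onset = None
                for d, r in zip(cands, rates):
                    acc += float(r)
                    if u < acc:
                        chosen_onset = d
                        break
                if chosen_onset is not None:
                    d = chosen_onset
                    if float(ti) >= day_end:  # rare: bumped past a boundary
                        roll_day_to(float(ti))
                    ties.add(d)
                    onset_at[d] = ti
                    ev = Event(ti, d, "onset", model, grid.day_index(ti), frozenset(ties))
                    events.append(ev)
                    counters.record(ev)
                    if decisions is not None and model in ("pair", "group"):
                        decisions.append(Decision(ti, model, cands, stats, d))
                else:
                    idx = int(rng.integers(len(ties)))
                    d = sorted(ties)[idx]
                    ti = max(ti, onset_at[d] + config.min_interval_s)
                    if float(ti) >= day_end:
                        roll_day_to(float(ti))
                    etype = {3: "triangle_dissolution", 2: "group_dissolution", 1: "pair_dissolution"}[len(ties)]
                    ties.discard(d)
                    events.append(
                        Event(ti, d, "offset", etype, grid.day_index(ti), frozenset(ties))
                    )
                    intervals.append(ContactInterval(d, onset_at.pop(d), ti))
                last_t = ti
                t = max(tau, float(ti))
        if t >= t_end:
            break
        roll_day_to(t)

    # monitoring ends: close whatever is still in contact, in dyad order
    for d in sorted(ties):
        ti = max(t_end, last_t + 1, onset_at[d] + config.min_interval_s)
        etype = {3: "triangle_dissolution", 2: "group_dissolution", 1: "pair_dissolution"}[len(ties)]
        ties.discard(d)
        events.append(Event(ti, d, "offset", etype, grid.day_index(ti), frozenset(ties)))
        intervals.append(ContactInterval(d, onset_at.pop(d), ti))
        last_t = ti

    intervals.sort(key=lambda iv: (iv.onset_t, iv.dyad))
    manifest = TriadManifest(
        triad_id=triad_id,
        id_map={f"{triad_id}.{c}": c for c in (1, 2, 3)},
        introduction=config.introduction,
    )
    records = logger_io.intervals_to_records(intervals, manifest)
    if config.reciprocal_noise:
        records = _with_reciprocal_duplicates(records, manifest, rng)
    stream = EventStream(events, grid=grid, triad_id=triad_id)
    return TriadSim(
        triad_id=triad_id,
        manifest=manifest,
        records=records,
        intervals=intervals,
        stream=stream,
        decisions=decisions,
        config=config,
    )


def _with_reciprocal_duplicates(
    records: Sequence[ContactRecord],
    manifest: TriadManifest,
    rng: np.random.Generator,
) -> list[ContactRecord]:
    """Add the partner collar's report of each contact with up to 2 s of
    inward boundary jitter.  Duplicates are subsets of the primary report, so
    reciprocal compression recovers exactly the primary intervals."""
    out = list(records)
    for r in records:
        a = int(rng.integers(0, 3))
        b = int(rng.integers(0, 3))
        if r.duration_s - a - b < 1:
            a = b = 0
        from datetime import timedelta

        out.append(
            ContactRecord(
                focal_id=r.partner_id,
                partner_id=r.focal_id,
                start=r.start + timedelta(seconds=a),
                end=r.end - timedelta(seconds=b),
                duration_s=r.duration_s - a - b,
            )
        )
    out.sort(key=lambda r: (r.start, r.focal_id))
    return out


def simulate_study(config: SimConfig, log_decisions: bool = False) -> Study:
    """Simulate ``config.n_triads`` independent triads with per-triad seeds
    derived from the master seed."""
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_triads)
    sims = []
    for i, sub in enumerate(seqs, start=1):
        sims.append(
            simulate_triad(
                config,
                np.random.default_rng(sub),
                triad_id=f"T{i:03d}",
                log_decisions=log_decisions,
            )
        )
    return Study(config=config, sims=sims)


def reingest(sim: TriadSim, min_duration_s: int | None = None) -> EventStream:
    """Run one simulated triad's logger records back through the full
    ingestion pipeline (parse → filter → compress → tie-break → classify)."""
    cfg = sim.config
    if min_duration_s is None:
        min_duration_s = cfg.min_interval_s
    text = logger_io.write_logger_text(sim.records)
    records = logger_io.parse_logger_file(text, sim.manifest)
    records = logger_io.filter_short_contacts(records, min_duration_s)
    intervals = logger_io.compress_reciprocal(records, sim.manifest)
    intervals = logger_io.break_onset_ties(intervals)
    from .events import build_event_stream

    return build_event_stream(intervals, grid=cfg.grid(), triad_id=sim.triad_id)
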