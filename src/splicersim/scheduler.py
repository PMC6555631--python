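"""Discrete-event simulation of gated multi-slice acquisition schedules.

Three families of schedules are simulated on a common event model:

* **Ungated** — slices are excited in fixed order at uniformly spaced slots
  (slot width TR / n_slices) and every excitation is retained.
* **SPLICER** — the same fixed slot grid, but each slice carries its own
  phase-encode loop counter.  The gate is evaluated at each excitation
  instant: while the gate is high RF is still applied (a dummy excitation,
  preserving the magnetisation steady state) but the counter freezes.  When a
  breath is detected, data acquired during the lookback window immediately
  before detection are discarded and the affected counters rewound, so those
  phase-encode steps are reacquired at the same index the next time the slice
  lands in a quiet period.  Every slice therefore sees an exactly constant
  TR, and the scan completes when all slices have kept their full complement
  of shots.
* **Conventional triggered** — the sequence is suspended after each block of
  slices and resumes on the (every-nth) breath trigger once the gate drops,
  so the realised TR is the sum of n instantaneous breath intervals and
  varies whenever breathing does.

Time bookkeeping: slot instants are integer multiples of the slot width
offset by the scan start time, while breaths live in continuous time, which
mirrors how a real sequencer polls the gate immediately before each slice.
A completed scan's duration is reported as (index of the slot holding the
final kept acquisition + 1) x slot width, i.e. the scanner stops right after
collecting the last good data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .respiration import (
    GateParams,
    RespModel,
    RespirationTrace,
    availability_fraction,
    detection_times,
    gate_intervals,
    generate_trace,
    unavailable_intervals,
)

__all__ = [
    "ScanConfig",
    "AcquisitionEvent",
    "EventLog",
    "ScanTimeStats",
    "run_ungated",
    "run_splicer",
    "run_triggered",
    "scan_time_stats",
    "completion_overhead",
    "subseed",
]

ACQUIRED = "acquired"
DUMMY = "dummy"
DISCARDED = "discarded"


@dataclass(frozen=True)
class ScanConfig:
    """Geometry and timing of a 2D multi-slice Cartesian scan.

    n_pe phase-encode lines per slice are collected in shots of ``etl`` lines
    (echo train length; 1 for gradient echo), so each slice needs
    ``n_pe // etl`` kept shots.  ``loop_cap_factor`` bounds the attempts per
    slice (kept plus discarded shots) at that multiple of the required count,
    emulating the enlarged projection loop that lets gated scans complete
    naturally on scanner hardware.
    """

    tr: float
    n_slices: int = 1
    n_pe: int = 128
    etl: int = 1
    loop_cap_factor: float = 4.0
    pe_ordering: Literal["linear", "centric"] = "linear"

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_pe < 1 or self.etl < 1 or self.n_pe % self.etl != 0:
            raise ValueError("n_pe must be a positive multiple of etl")
        if self.loop_cap_factor < 1:
            raise ValueError("loop_cap_factor must be >= 1")
        if self.pe_ordering not in ("linear", "centric"):
            raise ValueError("pe_ordering must be 'linear' or 'centric'")

    @property
    def shots_per_slice(self) -> int:
        return self.n_pe // self.etl

    @property
    def slot_width(self) -> float:
        return self.tr / self.n_slices

    def ungated_time(self, n_repeats: int = 1) -> float:
        """Scan time of the conventional ungated acquisition."""
        return n_repeats * self.shots_per_slice * self.n_slices * self.slot_width


@dataclass
class AcquisitionEvent:
    """One excitation of one slice.

    ``slot`` is the integer slot-grid index (slot-based schedules only; -1
    for triggered modes, whose excitations are not grid-aligned).  Dummy
    events carry the frozen counter value; discarded events were acquired and
    later invalidated by a breath detection.
    """

    time: float
    slice: int
    shot_index: int
    status: str
    slot: int = -1
    repeat: int = 0


@dataclass
class EventLog:
    """Complete, time-ordered record of a simulated scan."""

    events: list[AcquisitionEvent]
    scan_time: float
    completed: bool
    per_slice_shots_kept: np.ndarray
    config: ScanConfig
    start_time: float = 0.0
    mode: str = "ungated"

    def kept_events(self, slice_index: int | None = None) -> list[AcquisitionEvent]:
        return [
            e
            for e in self.events
            if e.status == ACQUIRED
            and (slice_index is None or e.slice == slice_index)
        ]

    def slice_excitation_times(self, slice_index: int) -> np.ndarray:
        """All excitation instants of one slice, any status, sorted."""
        return np.asarray(
            sorted(e.time for e in self.events if e.slice == slice_index)
        )

    def status_counts(self) -> dict[str, int]:
        out = {ACQUIRED: 0, DUMMY: 0, DISCARDED: 0}
        for e in self.events:
            out[e.status] += 1
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mode": self.mode,
            "scan_time": self.scan_time,
            "completed": self.completed,
            "start_time": self.start_time,
            "per_slice_shots_kept": self.per_slice_shots_kept.tolist(),
            "config": {
                "tr": self.config.tr,
                "n_slices": self.config.n_slices,
                "n_pe": self.config.n_pe,
                "etl": self.config.etl,
                "loop_cap_factor": self.config.loop_cap_factor,
                "pe_ordering": self.config.pe_ordering,
            },
            "events": [
                [e.time, e.slice, e.shot_index, e.status, e.slot, e.repeat]
                for e in self.events
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EventLog":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            events=[
                AcquisitionEvent(t, s, sh, st, slot, rep)
                for t, s, sh, st, slot, rep in d["events"]
            ],
            scan_time=d["scan_time"],
            completed=d["completed"],
            per_slice_shots_kept=np.asarray(d["per_slice_shots_kept"], dtype=int),
            config=ScanConfig(**d["config"]),
            start_time=d["start_time"],
            mode=d["mode"],
        )


def run_ungated(
    config: ScanConfig, n_repeats: int = 1, start_time: float = 0.0
) -> EventLog:
    """Conventional ungated multi-slice scan: every excitation is retained."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    w = config.slot_width
    events: list[AcquisitionEvent] = []
    k = 0
    for r in range(n_repeats):
        for j in range(config.shots_per_slice):
            for s in range(config.n_slices):
                events.append(
                    AcquisitionEvent(
                        time=start_time + k * w,
                        slice=s,
                        shot_index=j,
                        status=ACQUIRED,
                        slot=k,
                        repeat=r,
                    )
                )
                k += 1
    return EventLog(
        events=events,
        scan_time=k * w,
        completed=True,
        per_slice_shots_kept=np.full(
            config.n_slices, n_repeats * config.shots_per_slice
        ),
        config=config,
        start_time=start_time,
        mode="ungated",
    )


def _interval_edges(intervals: np.ndarray) -> np.ndarray:
    return np.asarray(intervals, dtype=float).reshape(-1)


def _inside(edges: np.ndarray, t: float) -> bool:
    """Point-in-union test for merged half-open intervals [lo, hi)."""
    return bool(np.searchsorted(edges, t, side="right") % 2)


def run_splicer(
    config: ScanConfig,
    trace: RespirationTrace,
    gate: GateParams,
    start_time: float = 0.0,
) -> EventLog:
    """Gated scan with per-slice loop counters and lookback reacquisition.

    Slices are excited on the fixed slot grid regardless of breathing, so the
    per-slice TR is exactly constant.  Gate-high slots become dummy
    excitations with frozen counters.  At each breath detection the shots
    acquired within the lookback window are discarded and the owning
    counters rewound, scheduling those shot indices for reacquisition.  The
    scan completes once every slice has kept ``shots_per_slice`` shots and no
    future detection can still invalidate them; it is flagged incomplete if
    any slice exhausts its attempt cap or the trace ends first.
    """
    needed = config.shots_per_slice
    cap_attempts = int(math.ceil(config.loop_cap_factor * needed))
    w = config.slot_width
    ns = config.n_slices
    lookback = gate.reacq_lookback

    det = detection_times(trace, gate)
    gate_edges = _interval_edges(gate_intervals(trace, gate))

    counters = [0] * ns
    attempts = [0] * ns
    kept = [0] * ns
    active: list[list[AcquisitionEvent]] = [[] for _ in range(ns)]
    events: list[AcquisitionEvent] = []
    det_idx = 0
    k = 0
    last_kept_slot = -1
    newest_kept_time = -math.inf
    completed = False

    while True:
        t = start_time + k * w
        if t > trace.total_duration:
            break  # trace exhausted before completion
        # apply every breath detection up to the current excitation instant
        while det_idx < det.size and det[det_idx] <= t:
            td = det[det_idx]
            lo = td - lookback
            for s in range(ns):
                doomed = [e for e in active[s] if lo <= e.time < td]
                if doomed:
                    for e in doomed:
                        e.status = DISCARDED
                    active[s] = [e for e in active[s] if e.status == ACQUIRED]
                    counters[s] -= len(doomed)
                    kept[s] -= len(doomed)
            det_idx += 1

        s = k % ns
        if kept[s] >= needed or _inside(gate_edges, t):
            # RF is applied but no data retained; the counter stays frozen
            events.append(
                AcquisitionEvent(
                    time=t, slice=s, shot_index=counters[s], status=DUMMY, slot=k
                )
            )
        else:
            if attempts[s] >= cap_attempts:
                break  # loop cap exceeded: premature termination
            ev = AcquisitionEvent(
                time=t, slice=s, shot_index=counters[s], status=ACQUIRED, slot=k
            )
            events.append(ev)
            active[s].append(ev)
            counters[s] += 1
            attempts[s] += 1
            kept[s] += 1
            last_kept_slot = k
            newest_kept_time = t

        if all(c >= needed for c in kept):
            next_det = det[det_idx] if det_idx < det.size else math.inf
            if next_det - lookback > newest_kept_time:
                completed = True
                break
        k += 1

    if completed:
        scan_time = (last_kept_slot + 1) * w
        # drop the trailing dummies emitted while confirming that no further
        # breath could invalidate the final shots: the scanner has stopped
        events = [e for e in events if e.slot <= last_kept_slot]
    else:
        scan_time = (k + 1) * w
    return EventLog(
        events=events,
        scan_time=scan_time,
        completed=completed,
        per_slice_shots_kept=np.asarray(kept),
        config=config,
        start_time=start_time,
        mode="splicer",
    )


def run_triggered(
    config: ScanConfig,
    trace: RespirationTrace,
    gate: GateParams,
    slices_per_block: int | None = None,
    intervals_per_tr: int | Literal["full_relaxation"] = 1,
    t1: float | None = None,
    start_time: float = 0.0,
    slice_duration: float | None = None,
) -> EventLog:
    """Conventional respiration-triggered scan (suspend-and-resume).

    After each block of ``slices_per_block`` slices the sequence is suspended
    until the gate falls following the selected breath trigger: every breath
    (``intervals_per_tr=1``), every 2nd breath (2), every nth breath (n), or
    the first breath for which the inter-block spacing reaches 5 T1
    (``"full_relaxation"``, requires ``t1``).  The realised TR is the trigger
    spacing and varies with the breathing.  Shots whose excitation lands in
    the next breath's unavailable window are discarded and retried on a later
    trigger; there is no counter-freezing or dummy excitation.
    """
    ns = config.n_slices
    spb = ns if slices_per_block is None else int(slices_per_block)
    if not (1 <= spb <= ns):
        raise ValueError("slices_per_block must be in [1, n_slices]")
    if intervals_per_tr == "full_relaxation":
        if t1 is None:
            raise ValueError("full_relaxation triggering requires t1")
        min_spacing = 5.0 * t1
        every_n = None
    else:
        every_n = int(intervals_per_tr)
        if every_n < 1:
            raise ValueError("intervals_per_tr must be >= 1")
        min_spacing = None
    sdur = config.slot_width if slice_duration is None else float(slice_duration)

    needed = config.shots_per_slice
    unavail_edges = _interval_edges(unavailable_intervals(trace, gate))
    block_starts = trace.onsets + trace.durations + gate.post_breath_extension

    groups = [
        list(range(g * spb, min((g + 1) * spb, ns)))
        for g in range(math.ceil(ns / spb))
    ]
    counters = [0] * ns
    events: list[AcquisitionEvent] = []
    group_idx = 0
    breaths_since = 0
    last_block = -math.inf
    end_time = start_time
    completed = False

    for b in range(trace.n_breaths):
        t0 = block_starts[b]
        if t0 < start_time:
            continue
        breaths_since += 1
        if every_n is not None:
            trigger = breaths_since >= every_n
        else:
            trigger = (t0 - last_block) >= min_spacing or last_block == -math.inf
        if not trigger:
            continue
        breaths_since = 0
        last_block = t0
        # skip groups that already finished
        for _ in range(len(groups)):
            if any(counters[s] < needed for s in groups[group_idx]):
                break
            group_idx = (group_idx + 1) % len(groups)
        t = t0
        for s in groups[group_idx]:
            if counters[s] >= needed:
                continue
            ok = not _inside(unavail_edges, t)
            events.append(
                AcquisitionEvent(
                    time=t,
                    slice=s,
                    shot_index=counters[s],
                    status=ACQUIRED if ok else DISCARDED,
                )
            )
            if ok:
                counters[s] += 1
                end_time = t + sdur
            t += sdur
        group_idx = (group_idx + 1) % len(groups)
        if all(c >= needed for c in counters):
            completed = True
            break

    return EventLog(
        events=events,
        scan_time=end_time - start_time,
        completed=completed,
        per_slice_shots_kept=np.asarray(counters),
        config=config,
        start_time=start_time,
        mode="triggered",
    )


def subseed(seed: int, index: int) -> np.random.SeedSequence:
    """Reproducible per-repeat seed: ``SeedSequence(seed, spawn_key=(index,))``."""
    return np.random.SeedSequence(seed, spawn_key=(index,))


@dataclass
class ScanTimeStats:
    """Monte-Carlo summary of SPLICER scan times over repeated traces."""

    mean: float
    sd: float
    n_repeats: int
    n_incomplete: int
    scan_times: np.ndarray = field(repr=False)
    extended_times: np.ndarray = field(repr=False)


def _trace_duration_needed(
    config: ScanConfig, model: RespModel, gate: GateParams, start_offset: float
) -> float:
    width = max(
        model.breath_duration
        + gate.post_breath_extension
        + gate.reacq_lookback
        - gate.detection_latency,
        0.0,
    )
    est_avail = max(1.0 - width / model.mu, 0.05)
    cap_time = config.loop_cap_factor * config.shots_per_slice * config.tr
    return start_offset + cap_time / est_avail + model.mu + 1.0


def _run_one(
    config: ScanConfig,
    model: RespModel,
    gate: GateParams,
    seed,
    start_at_breath_centre: bool,
) -> tuple[EventLog, RespirationTrace]:
    start = model.breath_duration / 2.0 if start_at_breath_centre else 0.0
    duration = _trace_duration_needed(config, model, gate, start)
    trace = generate_trace(model, duration, seed)
    log = run_splicer(config, trace, gate, start_time=start)
    return log, trace


def scan_time_stats(
    config: ScanConfig,
    model: RespModel,
    gate: GateParams,
    n_repeats: int,
    seed: int,
    start_at_breath_centre: bool = True,
) -> ScanTimeStats:
    """Mean and SD of SPLICER scan time over ``n_repeats`` independent traces.

    Each repeat draws a fresh trace from ``model`` with a per-repeat subseed
    and starts the scan clock at the centre of the first breath (the most
    favourable phase for scan/respiration synchrony), unless disabled.
    Incomplete scans are counted and excluded from the mean/SD, never dropped
    silently.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    times = np.empty(n_repeats)
    extended = np.empty(n_repeats)
    done = np.zeros(n_repeats, dtype=bool)
    for i in range(n_repeats):
        log, trace = _run_one(
            config, model, gate, subseed(seed, i), start_at_breath_centre
        )
        times[i] = log.scan_time
        frac = availability_fraction(trace, gate)
        extended[i] = math.inf if frac == 0 else config.ungated_time() / frac
        done[i] = log.completed
    ok = times[done]
    return ScanTimeStats(
        mean=float(ok.mean()) if ok.size else math.nan,
        sd=float(ok.std(ddof=1)) if ok.size > 1 else math.nan,
        n_repeats=n_repeats,
        n_incomplete=int(n_repeats - done.sum()),
        scan_times=times,
        extended_times=extended,
    )


def completion_overhead(
    config: ScanConfig,
    model: RespModel,
    gate: GateParams,
    n_repeats: int,
    seed: int,
    overhead: float = 0.10,
    start_at_breath_centre: bool = True,
) -> float:
    """Fraction of SPLICER scans completing within ``1 + overhead`` of the
    extended scan time.

    The extended scan time of each repeat is the ungated scan time divided by
    that realised trace's availability fraction — the natural lower bound for
    a gated scan.  Incomplete scans count as failures.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n_ok = 0
    for i in range(n_repeats):
        log, trace = _run_one(
            config, model, gate, subseed(seed, i), start_at_breath_centre
        )
        frac = availability_fraction(trace, gate)
        if frac == 0 or not log.completed:
            continue
        if log.scan_time <= (1.0 + overhead) * config.ungated_time() / frac:
            n_ok += 1
    return n_ok / n_repeats
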