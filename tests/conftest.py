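"""Shared fixtures and the independent brute-force replay oracle.

The oracle re-simulates the gated schedule event by event using only the
narrative rules (scan breath lists directly, quadratic discard search) and
none of the scheduler's internal machinery, so that agreement is a genuine
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pytest

from splicersim import GateParams, RespirationTrace, ScanConfig


@dataclass
class ReplayEvent:
    slot: int
    time: float
    slice: int
    shot_index: int
    status: str


def replay_splicer(
    config: ScanConfig,
    trace: RespirationTrace,
    gate: GateParams,
    start_time: float = 0.0,
) -> tuple[list[ReplayEvent], list[int], bool, float]:
    """Straightforward re-simulation of the gated schedule.

    Returns (events, kept_per_slice, completed, scan_time).
    """
    needed = config.n_pe // config.etl
    cap = int(math.ceil(config.loop_cap_factor * needed))
    w = config.tr / config.n_slices
    ns = config.n_slices

    breaths = list(zip(trace.onsets.tolist(), trace.durations.tolist()))
    detections = [on + gate.detection_latency for on, _ in breaths]

    def gate_high(t: float) -> bool:
        for (on, du), det in zip(breaths, detections):
            if det <= t < on + du + gate.post_breath_extension:
                return True
        return False

    events: list[ReplayEvent] = []
    counters = [0] * ns
    attempts = [0] * ns
    processed = 0
    k = 0
    last_kept_slot = -1
    newest_kept = -math.inf
    completed = False

    def kept_count(s: int) -> int:
        return sum(1 for e in events if e.slice == s and e.status == "acquired")

    while True:
        t = start_time + k * w
        if t > trace.total_duration:
            break
        while processed < len(detections) and detections[processed] <= t:
            td = detections[processed]
            for e in events:
                if e.status == "acquired" and td - gate.reacq_lookback <= e.time < td:
                    e.status = "discarded"
                    counters[e.slice] -= 1
            processed += 1
        s = k % ns
        if kept_count(s) >= needed or gate_high(t):
            events.append(ReplayEvent(k, t, s, counters[s], "dummy"))
        else:
            if attempts[s] >= cap:
                break
            events.append(ReplayEvent(k, t, s, counters[s], "acquired"))
            counters[s] += 1
            attempts[s] += 1
            last_kept_slot = k
            newest_kept = t
        if all(kept_count(s) >= needed for s in range(ns)):
            next_det = detections[processed] if processed < len(detections) else math.inf
            if next_det - gate.reacq_lookback > newest_kept:
                completed = True
                break
        k += 1

    if completed:
        scan_time = (last_kept_slot + 1) * w
        events = [e for e in events if e.slot <= last_kept_slot]
    else:
        scan_time = (k + 1) * w
    return events, [kept_count(s) for s in range(ns)], completed, scan_time


@pytest.fixture
def single_slice_config() -> ScanConfig:
    return ScanConfig(tr=2.0, n_slices=1, n_pe=128, etl=1)


@pytest.fixture
def rare_config() -> ScanConfig:
    return ScanConfig(tr=2.0, n_slices=4, n_pe=32, etl=8)
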