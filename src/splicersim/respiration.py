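"""Synthetic respiration traces and the gate logic derived from them.

An anaesthetised mouse takes snatched breaths of a few hundred milliseconds
separated by comparatively long quiescent periods; typical maintained rates
are 40-60 breaths/min, i.e. mean onset-to-onset intervals of 1.0-1.5 s.  The
scheduler only needs the event structure of respiration, not the analogue
pressure waveform, so a trace is reduced to breath-onset times and per-breath
motion durations.

Inter-breath intervals are drawn i.i.d. from a normal distribution about a
(possibly slowly drifting) mean and truncated below by redraw so that breaths
never overlap.  Occasional double breaths — a second breath following
immediately after the first — can be switched on as an extra onset shortly
after a breath completes.

Gating follows threshold detection on the pressure signal: the binary gate
(R-logic) goes high a short latency after breath onset and stays high until a
user-set extension beyond the end of breath motion.  Because the breath is
already in progress when detected, data acquired during a lookback window
immediately before each detection are discarded and reacquired; the union of
lookback, breath motion and post-breath extension is the per-breath window
that is unavailable for retained data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RespModel",
    "RespirationTrace",
    "GateParams",
    "ZERO_GATE",
    "empty_trace",
    "generate_trace",
    "detection_times",
    "gate_intervals",
    "unavailable_intervals",
    "availability_fraction",
    "merge_intervals",
]

#: minimum quiescent gap enforced between the end of one breath and the next
#: onset when redrawing truncated intervals (seconds)
MIN_GAP = 0.05

#: onset-to-onset spacing of the second breath of a double-breath pair is the
#: first breath's duration plus this gap (seconds)
DOUBLE_BREATH_GAP = 0.1

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class RespModel:
    """Statistical model of the breathing pattern.

    Parameters
    ----------
    mu : float
        Mean onset-to-onset inter-breath interval (seconds).
    sigma : float
        Standard deviation of the intervals (seconds, >= 0).
    breath_duration : float
        Duration of breath motion (seconds, > 0).
    drift_rate : float
        Linear change of the mean interval per unit time (s/s); models the
        slow respiration-rate drift seen under anaesthesia.
    double_breath_prob : float
        Probability that a breath is immediately followed by a second breath.
    """

    mu: float
    sigma: float
    breath_duration: float = 0.2
    drift_rate: float = 0.0
    double_breath_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= self.breath_duration:
            raise ValueError(
                f"mu ({self.mu}) must exceed breath_duration ({self.breath_duration})"
            )
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.breath_duration <= 0:
            raise ValueError("breath_duration must be > 0")
        if not (0 <= self.double_breath_prob < 1):
            raise ValueError("double_breath_prob must be in [0, 1)")


@dataclass(frozen=True)
class GateParams:
    """Timing of the R-logic gate relative to each breath.

    detection_latency is the delay from breath onset to threshold crossing;
    post_breath_extension keeps the gate high past the end of breath motion
    (the post-breath delay tau); reacq_lookback is the pre-detection window
    whose already-acquired data are discarded and reacquired.
    """

    detection_latency: float = 0.05
    post_breath_extension: float = 0.15
    reacq_lookback: float = 0.15

    def __post_init__(self) -> None:
        for name in ("detection_latency", "post_breath_extension", "reacq_lookback"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: gate with all margins zeroed: breath motion alone is the unavailable window
ZERO_GATE = GateParams(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class RespirationTrace:
    """Breath onsets and durations on a continuous time axis."""

    onsets: np.ndarray
    durations: np.ndarray
    total_duration: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if onsets.shape != durations.shape:
            raise ValueError("onsets and durations must have equal length")
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValueError("onsets must be strictly increasing")
            if np.any(np.diff(onsets) <= durations[:-1]):
                raise ValueError("inter-breath intervals must exceed breath durations")
            if onsets[0] < 0 or onsets[-1] > self.total_duration:
                raise ValueError("all onsets must lie within [0, total_duration]")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be > 0")

    @property
    def n_breaths(self) -> int:
        return int(self.onsets.size)

    def breath_intervals(self) -> np.ndarray:
        """(start, end) of breath motion for each breath, shape (n, 2)."""
        return np.column_stack([self.onsets, self.onsets + self.durations])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "onsets": self.onsets.tolist(),
            "durations": self.durations.tolist(),
            "total_duration": self.total_duration,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RespirationTrace":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            onsets=np.asarray(d["onsets"], dtype=float),
            durations=np.asarray(d["durations"], dtype=float),
            total_duration=float(d["total_duration"]),
            meta=d.get("meta", {}),
        )


def empty_trace(total_duration: float) -> RespirationTrace:
    """A breath-free trace (degenerate gate: everything is available)."""
    return RespirationTrace(
        onsets=np.empty(0), durations=np.empty(0), total_duration=total_duration
    )


def generate_trace(
    model: RespModel,
    duration: float,
    seed: int | np.random.SeedSequence | np.random.Generator,
    first_onset: float = 0.0,
) -> RespirationTrace:
    """Draw a respiration trace from ``model`` over ``[0, duration]``.

    Intervals are Normal(mu + drift_rate * t, sigma), redrawn while they do
    not exceed the current breath's duration plus a small quiescent gap.  The
    first breath onset is placed at ``first_onset`` (default 0).  Identical
    (seed, parameters) produce identical traces.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    onsets: list[float] = []
    durations: list[float] = []
    t = float(first_onset)
    while t < duration:
        onsets.append(t)
        durations.append(model.breath_duration)
        if model.double_breath_prob and rng.random() < model.double_breath_prob:
            t2 = t + model.breath_duration + DOUBLE_BREATH_GAP
            if t2 >= duration:
                break
            onsets.append(t2)
            durations.append(model.breath_duration)
            t = t2
        mu_t = model.mu + model.drift_rate * t
        lower = model.breath_duration + MIN_GAP
        if model.sigma == 0.0:
            interval = mu_t
            if interval <= lower:
                raise ValueError(
                    "deterministic interval does not exceed breath duration"
                )
        else:
            for _ in range(_MAX_REDRAWS):
                interval = rng.normal(mu_t, model.sigma)
                if interval > lower:
                    break
            else:
                raise RuntimeError(
                    "could not draw a positive inter-breath interval; "
                    "mu is too close to breath_duration for this sigma"
                )
        t += interval
    return RespirationTrace(
        onsets=np.asarray(onsets),
        durations=np.asarray(durations),
        total_duration=float(duration),
        meta={
            "mu": model.mu,
            "sigma": model.sigma,
            "breath_duration": model.breath_duration,
            "drift_rate": model.drift_rate,
            "double_breath_prob": model.double_breath_prob,
            "first_onset": first_onset,
        },
    )


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping or touching half-open intervals; returns sorted (n, 2)."""
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if iv.shape[0] == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].copy()]
    for lo, hi in iv[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append(np.array([lo, hi]))
    return np.asarray(merged)


def _check_latency(trace: RespirationTrace, gate: GateParams) -> None:
    if trace.n_breaths and gate.detection_latency >= float(trace.durations.min()):
        raise ValueError(
            "detection_latency must be shorter than the shortest breath duration"
        )


def detection_times(trace: RespirationTrace, gate: GateParams) -> np.ndarray:
    """Threshold-crossing instants: breath onset plus detection latency."""
    _check_latency(trace, gate)
    return trace.onsets + gate.detection_latency


def gate_intervals(trace: RespirationTrace, gate: GateParams) -> np.ndarray:
    """Gate-high (R-logic high) intervals, merged and sorted, shape (n, 2).

    Each breath raises the gate from detection until breath completion plus
    the post-breath extension: ``[onset + latency, onset + duration + ext)``.
    """
    _check_latency(trace, gate)
    if trace.n_breaths == 0:
        return np.empty((0, 2))
    lo = trace.onsets + gate.detection_latency
    hi = trace.onsets + trace.durations + gate.post_breath_extension
    return merge_intervals(np.column_stack([lo, hi]))


def unavailable_intervals(trace: RespirationTrace, gate: GateParams) -> np.ndarray:
    """Windows whose data are never retained, merged and sorted, shape (n, 2).

    Per breath this spans from lookback before detection to the end of the
    gate: ``[detection - reacq_lookback, onset + duration + ext)``.  Data
    acquired inside are either skipped (gate high) or discarded and
    reacquired (lookback window).
    """
    _check_latency(trace, gate)
    if trace.n_breaths == 0:
        return np.empty((0, 2))
    det = trace.onsets + gate.detection_latency
    lo = det - gate.reacq_lookback
    hi = trace.onsets + trace.durations + gate.post_breath_extension
    return merge_intervals(np.column_stack([lo, hi]))


def availability_fraction(trace: RespirationTrace, gate: GateParams) -> float:
    """Fraction of ``[0, total_duration]`` outside the unavailable windows.

    The reciprocal is the extended-scan-time multiple: the factor by which a
    gated scan is stretched relative to ungated scanning of the same data.
    """
    if trace.total_duration <= 0:
        raise ValueError("total_duration must be > 0")
    iv = unavailable_intervals(trace, gate)
    if iv.shape[0] == 0:
        return 1.0
    lo = np.clip(iv[:, 0], 0.0, trace.total_duration)
    hi = np.clip(iv[:, 1], 0.0, trace.total_duration)
    blocked = float(np.sum(hi - lo))
    return 1.0 - blocked / trace.total_duration
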