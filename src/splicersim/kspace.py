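"""Render a moving 2D phantom through an acquisition schedule into k-space.

The motion-artefact mechanism simulated here is the classic Cartesian
spin-warp one: phase-encode lines are collected at different times, so any
inconsistency between lines — a bulk displacement during a breath, or a
shot-to-shot amplitude modulation from variable T1 weighting — replicates the
object along the phase-encode axis as ghosting.

Motion enters as a rigid displacement along the phase-encode axis applied via
the Fourier shift theorem (a per-line linear phase), which is exact for bulk
translation and keeps the simulated k-space free of rasterisation artefacts
that would confound the ghost metric.  Shot amplitudes come from the
longitudinal-recovery recursion over each slice's realised excitation train:
schedules that keep TR exactly constant (ungated, SPLICER) produce constant
amplitudes, while suspend-and-resume triggered schedules produce variable
amplitudes whenever breathing varies.

Axes: array index 0 is phase encode, index 1 is readout.  k-space is stored
with the DC line at row ``n_pe // 2`` (fftshift convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .respiration import RespirationTrace
from .scheduler import ACQUIRED, EventLog, ScanConfig
from .signal_model import RelaxationParams, recovery_amplitudes, steady_state_mz

__all__ = [
    "Ellipse",
    "Phantom",
    "default_phantom",
    "MotionModel",
    "displacement_at",
    "pe_line_for",
    "KSpaceData",
    "acquire",
    "shot_amplitudes",
    "reconstruct",
    "ghost_to_signal_ratio",
]


@dataclass(frozen=True)
class Ellipse:
    """Uniform-intensity ellipse: centre/axes in mm, angle in degrees."""

    centre: tuple[float, float]
    axes: tuple[float, float]
    angle: float = 0.0
    intensity: float = 1.0
    t1: float | None = None

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if min(self.axes) <= 0:
            raise ValueError("ellipse axes must be > 0")


@dataclass(frozen=True)
class Phantom:
    """Additive-ellipse 2D phantom on a square matrix.

    ``matrix`` pixels span ``fov`` mm in each direction; pixel centres sit at
    ``(i - matrix/2) * fov/matrix``.  Ellipses must lie inside the FOV.
    """

    matrix: int
    fov: float
    ellipses: tuple[Ellipse, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        half = self.fov / 2.0
        for e in self.ellipses:
            reach = max(e.axes)
            if (
                abs(e.centre[0]) + reach > half
                or abs(e.centre[1]) + reach > half
            ):
                raise ValueError(f"ellipse {e} extends beyond the field of view")

    @property
    def pixel_size(self) -> float:
        return self.fov / self.matrix

    def _grid(self) -> tuple[np.ndarray, np.ndarray]:
        c = (np.arange(self.matrix) - self.matrix // 2) * self.pixel_size
        return np.meshgrid(c, c, indexing="ij")  # (pe, read)

    def rasterize(self) -> np.ndarray:
        """Pixel-centre sampled intensity image, shape (matrix, matrix)."""
        yy, xx = self._grid()
        img = np.zeros((self.matrix, self.matrix))
        for e in self.ellipses:
            th = math.radians(e.angle)
            dx = xx - e.centre[1]
            dy = yy - e.centre[0]
            u = dx * math.cos(th) + dy * math.sin(th)
            v = -dx * math.sin(th) + dy * math.cos(th)
            img += e.intensity * (
                (u / e.axes[1]) ** 2 + (v / e.axes[0]) ** 2 <= 1.0
            )
        return img

    def support_mask(self) -> np.ndarray:
        return self.rasterize() > 0

    def kspace(self) -> np.ndarray:
        """Static k-space: centred 2D FFT of the rasterised phantom."""
        return image_to_kspace(self.rasterize())


def default_phantom(matrix: int = 64, fov: float = 32.0) -> Phantom:
    """A mouse-abdomen-like test object: body outline, paired kidneys, lesion.

    The body ellipse fills roughly half the FOV along phase encode so that
    the out-of-object rows used by the ghost metric remain wide.
    """
    return Phantom(
        matrix=matrix,
        fov=fov,
        ellipses=(
            Ellipse(centre=(0.0, 0.0), axes=(8.0, 11.0), intensity=0.6),
            Ellipse(centre=(-2.0, -4.5), axes=(3.0, 2.0), angle=15.0, intensity=0.5),
            Ellipse(centre=(-2.0, 4.5), axes=(3.0, 2.0), angle=-15.0, intensity=0.5),
            Ellipse(centre=(4.0, 1.5), axes=(1.6, 1.6), intensity=0.9),
        ),
    )


@dataclass(frozen=True)
class MotionModel:
    """Breath-locked bulk displacement along the phase-encode axis.

    The waveform is a raised-cosine bump supported exactly on each breath
    motion interval, peaking at ``amplitude`` mm at the breath centre and
    identically zero between breaths.
    """

    amplitude: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def displacement_at(
    motion: MotionModel, trace: RespirationTrace, t
) -> float | np.ndarray:
    """Displacement (mm) at time(s) ``t``: zero outside breath intervals,
    ``amplitude * (1 - cos(2 pi (t - onset)/duration)) / 2`` inside."""
    tt = np.asarray(t, dtype=float)
    out = np.zeros_like(tt)
    if trace.n_breaths:
        idx = np.searchsorted(trace.onsets, tt, side="right") - 1
        valid = idx >= 0
        i = np.clip(idx, 0, trace.n_breaths - 1)
        onset = trace.onsets[i]
        dur = trace.durations[i]
        inside = valid & (tt >= onset) & (tt < onset + dur)
        phase = np.where(dur > 0, (tt - onset) / np.where(dur > 0, dur, 1.0), 0.0)
        out = np.where(
            inside, motion.amplitude * (1.0 - np.cos(2.0 * np.pi * phase)) / 2.0, 0.0
        )
    return float(out) if np.isscalar(t) or out.ndim == 0 else out


def pe_line_for(shot_index: int, echo_index: int, config: ScanConfig) -> int:
    """Phase-encode line collected by echo ``echo_index`` of shot
    ``shot_index``.

    Linear-segmented ordering assigns line ``echo * n_shots + shot``; centric
    ordering ranks all lines by distance from the k-space centre and deals
    them out in that order, so the most central line of every shot's echo
    train falls on echo 0.  Both are bijections covering all n_pe lines.
    """
    n_shots = config.shots_per_slice
    if not (0 <= shot_index < n_shots) or not (0 <= echo_index < config.etl):
        raise IndexError(
            f"shot {shot_index} / echo {echo_index} out of range for "
            f"{n_shots} shots x ETL {config.etl}"
        )
    if config.pe_ordering == "linear":
        return echo_index * n_shots + shot_index
    # centric: stable sort by |k - centre| puts the DC line first
    centre = config.n_pe // 2
    order = sorted(range(config.n_pe), key=lambda k: (abs(k - centre), k))
    return order[echo_index * n_shots + shot_index]


@dataclass
class KSpaceData:
    """Complex k-space per slice with per-line provenance."""

    data: np.ndarray  # (n_slices, n_pe, n_read) complex
    line_time: np.ndarray  # (n_slices, n_pe)
    line_shot: np.ndarray  # (n_slices, n_pe) int
    filled: np.ndarray  # (n_slices, n_pe) bool
    fov: float
    config: ScanConfig = field(repr=False)


def image_to_kspace(img: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def kspace_to_image(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k)))


def acquire(
    phantom: Phantom,
    eventlog: EventLog,
    motion: MotionModel | None = None,
    trace: RespirationTrace | None = None,
    relax: RelaxationParams | None = None,
    echo_spacing: float = 0.0,
    repeat: int | None = None,
    normalize: bool = True,
) -> KSpaceData:
    """Fill k-space from the kept shots of a completed schedule.

    Each kept shot contributes ``etl`` phase-encode lines of the static
    phantom k-space, multiplied by (a) the shot's longitudinal-recovery
    amplitude over the slice's full realised excitation train — dummy and
    discarded excitations included, since RF is applied during breaths — and
    (b) a per-line linear phase encoding the bulk displacement at that line's
    acquisition instant.  Lines from discarded events never appear; with
    ``normalize`` each slice is scaled by its mean kept-shot amplitude so
    that receiver gain does not enter the artefact metrics.

    For multi-repeat ungated logs pass ``repeat`` to select one repeat.
    """
    if not eventlog.completed:
        raise ValueError("eventlog is incomplete: refusing to reconstruct")
    config = eventlog.config
    if config.n_pe != phantom.matrix:
        raise ValueError("config.n_pe must match the phantom matrix")
    if motion is not None and trace is None:
        raise ValueError("motion requires the respiration trace")

    n_pe = config.n_pe
    k0 = phantom.kspace()
    kc = np.arange(n_pe) - n_pe // 2

    data = np.zeros((config.n_slices, n_pe, phantom.matrix), dtype=complex)
    line_time = np.full((config.n_slices, n_pe), np.nan)
    line_shot = np.full((config.n_slices, n_pe), -1, dtype=int)
    filled = np.zeros((config.n_slices, n_pe), dtype=bool)

    for s in range(config.n_slices):
        times_all = eventlog.slice_excitation_times(s)
        if relax is not None:
            spacing = (
                float(np.median(np.diff(times_all)))
                if times_all.size > 1
                else config.tr
            )
            amps_all = recovery_amplitudes(
                times_all, relax, m_start=steady_state_mz(spacing, relax)
            )
            amp_of = dict(zip(times_all.tolist(), amps_all.tolist()))
        else:
            amp_of = None

        kept = [
            e
            for e in eventlog.events
            if e.slice == s
            and e.status == ACQUIRED
            and (repeat is None or e.repeat == repeat)
        ]
        amps_used = []
        for ev in kept:
            amp = 1.0 if amp_of is None else amp_of[ev.time]
            amps_used.append(amp)
            for ei in range(config.etl):
                line = pe_line_for(ev.shot_index, ei, config)
                if filled[s, line]:
                    raise ValueError(
                        f"phase-encode line {line} of slice {s} filled twice"
                    )
                t_line = ev.time + ei * echo_spacing
                if motion is not None:
                    d = displacement_at(motion, trace, t_line)
                    ramp = np.exp(-2j * np.pi * kc[line] * d / phantom.fov)
                else:
                    ramp = 1.0
                data[s, line, :] = k0[line, :] * amp * ramp
                line_time[s, line] = t_line
                line_shot[s, line] = ev.shot_index
                filled[s, line] = True
        if normalize and amps_used and amp_of is not None:
            data[s] /= float(np.mean(amps_used))

    return KSpaceData(
        data=data,
        line_time=line_time,
        line_shot=line_shot,
        filled=filled,
        fov=phantom.fov,
        config=config,
    )


def shot_amplitudes(
    eventlog: EventLog, relax: RelaxationParams, slice_index: int = 0
) -> np.ndarray:
    """Recovery amplitude of each kept shot of one slice, in k-space fill
    order — the quantity whose shot-to-shot variation drives T1-weighting
    ghosts."""
    times_all = eventlog.slice_excitation_times(slice_index)
    spacing = (
        float(np.median(np.diff(times_all)))
        if times_all.size > 1
        else eventlog.config.tr
    )
    amps_all = recovery_amplitudes(
        times_all, relax, m_start=steady_state_mz(spacing, relax)
    )
    amp_of = dict(zip(times_all.tolist(), amps_all.tolist()))
    return np.asarray(
        [amp_of[e.time] for e in eventlog.kept_events(slice_index)]
    )


def reconstruct(kspace: KSpaceData) -> np.ndarray:
    """Magnitude image per slice via centred 2D inverse FFT.

    Refuses k-space with any unfilled phase-encode line.
    """
    if not kspace.filled.all():
        missing = int((~kspace.filled).sum())
        raise ValueError(f"k-space incomplete: {missing} unfilled lines")
    return np.abs(np.stack([kspace_to_image(k) for k in kspace.data]))


def ghost_to_signal_ratio(image: np.ndarray, object_mask: np.ndarray) -> float:
    """Mean magnitude over out-of-object phase-encode rows relative to the
    mean magnitude inside the object.

    Ghost replicas propagate along the phase-encode axis (axis 0), so the
    artefact band is taken as every row with no object support, across the
    full read width.
    """
    img = np.asarray(image, dtype=float)
    mask = np.asarray(object_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        raise ValueError("object mask is empty")
    ghost_rows = ~mask.any(axis=1)
    if not ghost_rows.any():
        raise ValueError("no object-free rows available for the ghost band")
    return float(img[ghost_rows, :].mean() / img[mask].mean())
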