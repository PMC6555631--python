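# Models and methods

This note documents the models the simulator implements, the parameters that
matter, the numerical choices, and what the synthetic studies do and do not
show about real scans.

## Signal model

SNR-per-unit-time efficiency assumes signal averaging: acquiring for time T
at repetition time TR yields T/TR averages of amplitude A(TR), so SNR per
unit time ∝ A(TR)/√TR. For a 90° spin echo A = 1 − exp(−TR/T1) and the
efficiency `(1 − e^(−x))/√x` (x = TR/T1) has a single interior maximum at
the root of `exp(x) = 2x + 1`, x* = 1.2564, found by bracketed root finding
(brentq, xtol 1e−12). For spoiled gradient echo the Ernst steady-state
amplitude `sinθ (1 − E)/(1 − E cosθ)`, E = exp(−TR/T1), replaces the
saturation-recovery term and the optimum is located by bounded 1-D
maximisation on x ∈ (1e−6, 10] with xatol 1e−6 — reproducible to the quoted
2-decimal values without any seed. Echo amplitude is evaluated at the
excitation; T2 decay and the echo-train amplitude evolution are out of scope.

Transient trains use the longitudinal recursion: Mz ← Mz·cosθ at each pulse,
relaxation toward 1 with time constant T1 between pulses, emitted amplitude
Mz·sinθ. Perfect spoiling is assumed (no transverse history), because the
ghosting mechanism of interest is T1-weighting modulation from a variable
TR, not coherence effects. `recovery_amplitudes` starts from equilibrium
(Mz = 1) by default; the k-space simulator instead starts each slice from
the steady state of its median realised spacing, emulating the dummy cycles
a scanner runs before acquisition — otherwise the first-shot transient would
masquerade as motion artefact. Flip angles are accepted in degrees
throughout.

## Respiration model

A trace is the event structure of breathing: onset times plus per-breath
motion durations. Inter-breath intervals are i.i.d. Normal(μ + drift·t, σ)
truncated below at `breath_duration + 0.05 s` **by redraw** (not clipping),
which preserves the mean approximately while guaranteeing positive quiet
gaps. Defaults emulate an anaesthetised mouse: μ 1.0–1.5 s (40–60
breaths/min), breath duration 0.2 s, σ ≈ 10 % of μ. Optional linear drift
models the slow rate change under anaesthesia; optional double breaths add a
second onset 0.1 s after a breath ends with a configurable probability
(default 0). The first onset sits at t = 0; Monte-Carlo runs start the scan
clock at the centre of the first breath, the most favourable phase for
maintaining scan/respiration synchrony and hence a conservative choice for
overhead statistics.

Gate logic mirrors threshold detection on a pressure signal: the gate goes
high `detection_latency` (default 50 ms — the breath is already in progress
when detected; the exact latency is hardware-dependent and configurable)
after onset and stays high until breath end plus `post_breath_extension`
(default 150 ms). Data acquired within `reacq_lookback` (default 150 ms)
before each detection are discarded and reacquired. The per-breath
unavailable window is therefore
`[detection − lookback, onset + duration + extension)`; with the default
margins and a 200 ms breath it spans 500 ms. The availability fraction —
time outside these windows over total time — sets the **extended scan
time**: ungated time / availability, the natural lower bound for any gated
scan. All intervals are half-open, merged when overlapping.

## Scheduler

Time is discretised on the slot grid `TR / n_slices`; slot k excites slice
k mod n_slices, and breaths live in continuous time. The gate is evaluated
at each excitation instant, as a real sequencer polls it immediately before
each slice. In the gated (SPLICER) mode a gate-high slot becomes a dummy
excitation (RF applied, counter frozen); a gate-low slot acquires the
slice's current shot and increments its counter; at each detection the shots
acquired within the lookback window are re-marked discarded and the counters
rewound, so the same shot indices are reacquired at later clean slots.
Because excitation never pauses, successive excitations of a slice are
always exactly one TR apart — the property that preserves the steady state
and any fixed-interval magnetisation preparation. Reacquisition granularity
is the whole shot (a RARE echo train is indivisible).

Attempts per slice (kept + discarded) are capped at
`loop_cap_factor × shots_per_slice` (default 4×, the enlarged projection
loop that lets real scans complete naturally); exceeding the cap, or running
off the end of the trace, flags the scan incomplete. A completed scan's
time is `(slot of final kept acquisition + 1) × slot width`. With a nonzero
lookback the simulator additionally waits until no future detection can
invalidate the final shots before declaring completion, so the invariant
"no kept datum lies in an unavailable window" holds over the entire trace;
a real scanner simply stops, accepting possibly breath-corrupted tail data.

Conventional triggered modes suspend the sequence after each block of slices
and resume when the gate falls after every nth breath (n = 1, 2, or chosen
for full relaxation, inter-block spacing ≥ 5 T1). Their realised TR is the
trigger spacing: constant only for clockwork breathing, variable otherwise —
the variable-T1-weighting ghost mechanism. Shots colliding with the next
breath's unavailable window are discarded and retried on a later trigger.

Monte-Carlo statistics (`scan_time_stats`, `completion_overhead`) run
independent traces with per-repeat subseeds `SeedSequence(seed,
spawn_key=(i,))`; incomplete scans are counted and reported, never silently
dropped (the mean/SD are over completed scans; `completion_overhead` counts
them as failures). Sweep-style runs zero the gate margins and treat the
whole 0.5 s breath-motion window as the unavailable window, matching the
convention in which "breath motion duration" already includes the margins.

## k-space simulator

The phantom is a sum of uniform ellipses rasterised at pixel centres (the
default object is a mouse-abdomen-like body outline with paired kidneys and
a small bright lesion, filling about half the FOV so ghost-band rows exist).
Its static k-space is the centred 2D FFT of the rasterised image; this keeps
the motion-free pipeline an exact identity (reconstruction error ~1e−16),
so any measured ghost is attributable to the schedule. Respiratory motion is
a rigid displacement along the phase-encode axis, a raised-cosine bump
supported exactly on each breath interval with peak `amplitude` (default
2 mm), applied per line via the Fourier shift theorem — exact for bulk
translation and free of re-rendering artefacts. Through-slice motion (and
hence wrong-slice excitation during breaths) is not simulated.

Each kept shot fills its echo train's lines (linear-segmented ordering
`line = echo·n_shots + shot`, or centric, which deals lines out in order of
distance from the k-space centre; both bijective) with the static line
scaled by the shot's recovery amplitude — computed over the slice's full
excitation train, dummy excitations included, since RF continues during
breaths — and the per-line motion phase ramp. Slices are normalised by
their mean kept-shot amplitude (receiver gain is arbitrary). The
ghost-to-signal ratio is the mean magnitude over all object-free
phase-encode rows (full read width, since ghosts replicate along PE only)
divided by the mean magnitude inside the object support.

## Temporal stability

Temporal SNR is per-pixel mean / sample SD (n−1 denominator, appropriate for
the small repeat counts of 10–20) over the repeat axis; zero-SD pixels are
flagged non-finite and masked rather than clipped, to avoid fabricated
infinite SNR in noise-free simulations. The enhancement map is the pixelwise
SNR ratio of two co-registered equal-time protocols (no registration is
performed). ROI summaries report both conventions for non-finite pixels:
excluded, and counted as unity (as signal voids register in an enhancement
map). The SNR↔time equivalence is `ratio²`, from SNR ∝ √time under
averaging. Stacks and maps round-trip through NIfTI-1 with pixel geometry in
the affine.

The demo experiment acquires 20 ungated and 10 gated repeats of the moving
phantom with additive complex k-space noise (image-domain SD 0.02, giving
object SNR of order 30); with the default breathing (availability ≈ 0.55)
the two protocols occupy virtually identical total time (within ~10–25 %,
whole-repeat granularity permitting). Temporal SD does not shrink with the
number of repeats, so the enhancement isolates the motion-driven variance
that gating removes.

## What the synthetic studies show — and don't

Problem sizes are chosen for desk-scale runs: 64–128 phase encodes, single
or few slices, 50–1000 Monte-Carlo repeats, 10×40 sweep grids (the
full-scale sweep grid of 100 σ × 200 TR × 1000 repeats is configurable).
The synthetic respiration model is stationary apart from optional linear
drift; real traces drift irregularly and include posture-dependent changes,
so the simulated completion-overhead percentage (typically ~100 % at 10 %
interval variability) supports, but does not measure, the in-vivo claim.
The phantom experiments demonstrate the *mechanisms* — phase-encode ghosting
from intra-scan motion and variable T1 weighting, and their removal by
constant-TR gating with reacquisition — not in-vivo effect sizes: the
measured enhancement depends on motion amplitude, noise level and geometry,
and only its direction (ROI-mean enhancement > 1, gated ghost < ungated
ghost in every paired trial) transfers. Pulsatile flow, gut motion, cardiac
gating, coil sensitivities, non-Cartesian trajectories and CPMG
phase-coherence loss are out of scope.
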