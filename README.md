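# splicersim

A desk-scale simulator of **SPLICER** (Slice Projection Loop Index Counter
Enabled Reacquisition), a prospective respiratory-gating acquisition scheme
for multi-slice MRI of free-breathing small animals.

## The problem

Abdominal and thoracic MRI in mice is corrupted by respiration: an
anaesthetised mouse takes snatched breaths of ~200 ms at 40–60 breaths/min,
and any phase-encode line collected during (or amplitude-modulated by) a
breath turns into ghosting along the phase-encode axis. Conventional
triggered scanning suspends the sequence between breaths, which forces the
repetition time TR to be an integer number of breath intervals — long,
variable, and far from the SNR-per-unit-time optimum. For a 90° spin echo
that optimum is at

    TR = 1.26 T1,   where x* = argmax (1 − e^(−x)) / √x,  x = TR/T1,

a 44 % efficiency gain over fully relaxed scanning at TR = 5 T1 (for
spoiled gradient echo at flip angles below 45° the optimum falls below
0.33 T1).

SPLICER scans every slice continually at a fixed TR of choice. Each slice
owns its phase-encode loop counter; while the respiration gate is high, RF
keeps firing (preserving the steady state) but the counters freeze, and data
acquired during a lookback window just before each breath detection are
discarded and reacquired. Only motion-clean data are spliced into k-space.
The cost is a scan-time extension by the reciprocal of the fraction of time
available between breaths, plus a small scheduling overhead.

This package is for pulse-sequence developers and preclinical imaging
scientists who want to study the scheme's scheduling behaviour, artefact
suppression and efficiency without a scanner: it simulates respiration
traces, gated/triggered/ungated schedules, k-space rendering of a moving
phantom, and the temporal-SNR analysis used to quantify stability. No
external data are required; user-supplied repeated-acquisition stacks in
NIfTI-1 can be analysed with the `stats` command.

## Worked example

```python
import numpy as np
from splicersim import (
    RespModel, ScanConfig, ZERO_GATE, completion_overhead,
    generate_trace, availability_fraction, optimum_tr_spin_echo,
)

# SNR-per-unit-time optimum for a 90-degree spin echo
print(round(optimum_tr_spin_echo(), 2))            # 1.26

# Deterministic breathing: 0.5 s breaths every 2.0 s blocks 25% of the time,
# so a gated scan stretches by 1/0.75 = 1.33x
model = RespModel(mu=2.0, sigma=0.0, breath_duration=0.5)
trace = generate_trace(model, 120.0, seed=0)
print(round(1 / availability_fraction(trace, ZERO_GATE), 2))   # 1.33

# 1000 Monte-Carlo gated scans of 128 projections at TR 2 s with
# N(1.5 s, 0.15 s) breathing: fraction finishing within 10% of the
# extended scan time
cfg = ScanConfig(tr=2.0, n_slices=1, n_pe=128, etl=1)
model = RespModel(mu=1.5, sigma=0.15, breath_duration=0.5)
print(completion_overhead(cfg, model, ZERO_GATE, n_repeats=1000, seed=1))  # 1.0
```

The last number says that with realistic (10 %) breath-interval variability
essentially every gated scan finishes within a 10 % overhead of the extended
scan time — the scheme's efficiency claim.

Command-line entry points (`splicer-sim --help`):

```bash
splicer-sim optimum-tr --t1 1.0 --flip 45      # optimum TR table
splicer-sim trace --mu 1.5 --sigma 0.15 --out trace.json
splicer-sim sweep --out sweep_out/             # (TR, sigma) scan-time maps
splicer-sim demo  --out demo_out/              # gated vs ungated phantom stacks
splicer-sim stats --stack demo_out/splicer_stack.nii.gz --out maps/
```

`demo` writes 4D NIfTI repeat stacks for ungated (20 repeats) and gated
(10 repeats, virtually identical total time) acquisitions of a moving
phantom, their mean/SD/temporal-SNR maps, the SNR enhancement map and a
circular-ROI summary CSV. On the defaults the ROI-mean enhancement is well
above 1: constant-TR gated scanning removes the motion-driven temporal
variance that signal averaging cannot recover. An SNR enhancement of r is
worth an r² scan-time saving (`snr_time_equivalence`).

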