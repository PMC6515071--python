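# gaitwave

Wavelet-scale-optimized detection of gait events from a single waist-worn
accelerometer.

A single inertial sensor at the lumbar spine is the cheapest practical way
to instrument gait, but the two events that anchor every spatiotemporal
gait parameter — the **initial contact** (IC, heel strike) and the **final
contact** (FC, toe off) — are hard to time reliably from one vertical
acceleration channel. A well-established approach integrates the vertical
acceleration and differentiates it with a continuous wavelet transform
(CWT) using a first-derivative-of-Gaussian (gaus1) mother wavelet:

    y_w(a, τ) = ∫ y(t) (1/√a) ψ((t − τ)/a) dt,    ψ(t) = −C t e^(−t²/2)

which acts as a *smoothed differentiator*: ICs are the minima of the
smoothed acceleration after one differentiation, FCs the maxima of the
smoothed jerk after a second. The catch is the wavelet **scale** `a`: it
sets the smoothing bandwidth (pseudo-frequency `f = fs·0.2/a`), and the
best choice depends on walking speed — strongly so for FCs.

`gaitwave` implements the full analysis around that question:

- calibrated gaus1 CWT differentiation (`gaitwave.cwt`),
- the IC/FC detection chain (`gaitwave.events`),
- tolerance-window matching against reference events with sensitivity,
  precision, F1, timing RMSE and the compact cost
  `T = 1 − (1 − RMSE_N)·F1` (`gaitwave.metrics`),
- scale sweeps (1–100), optimal-scale selection by minimum `T`, and linear
  regression of the optimal scale / pseudo-frequency on step frequency,
  enabling adaptive per-step scale selection (`gaitwave.optimize`),
- a synthetic lumbar-acceleration generator with exact ground-truth events
  and realistic cohort statistics for three self-selected walking speeds
  (`gaitwave.simulate`),
- text-based I/O and a `gaitwave` command-line interface
  (`gaitwave.io`, `gaitwave.cli`).

## Worked example

```python
import numpy as np
from gaitwave import detect, match_events, compute_metrics
from gaitwave.simulate import GaitParams, generate_trial
from gaitwave.pipeline import materialize

st = generate_trial(GaitParams.for_condition("normal"), seed=11)
trials, refs = materialize([st], fs_target=250.0)   # resample 102.4 -> 250 Hz

events = detect(trials[0], ic_scale=29, fc_scale=29)
print("IC est :", np.round(events.ic_times, 3))
print("IC true:", np.round(refs[0].ic_times, 3))

m = compute_metrics(match_events(events.ic_times, refs[0].ic_times, 0.050))
print(f"F1 {m.f1:.2f}  RMSE {m.rmse*1000:.1f} ms  T {m.t_cost:.3f}")
```

Output:

```
IC est : [1.068 1.612 2.16  2.72  3.424]
IC true: [1.07  1.605 2.161 2.716]
F1 0.89  RMSE 4.3 ms  T 0.187
```

All four ICs of the two central strides are found within a few
milliseconds of the ground truth; one noise-induced extremum in the
lead-out region survives as a false positive, which is exactly what the
precision term of `T` penalizes: `T` combines the timing error (normalized
to the 50 ms matching tolerance) with the F1 score, and is the quantity
the scale sweep minimizes. The same pipeline is available from the
shell: `gaitwave simulate`, `gaitwave detect`, `gaitwave sweep`,
`gaitwave optimize`, `gaitwave evaluate` (see `--help`).

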