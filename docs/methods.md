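# Methods

## Detection model

The detector follows the integrate-then-CWT-differentiate scheme for
waist-level vertical acceleration. With `y(t)` the mean-removed vertical
acceleration and `v(t)` its cumulative trapezoidal integral (a
velocity-like trace), the single-scale CWT

    y_w(a, τ) = ∫ v(t) (1/√a) ψ((t − τ)/a) dt,   ψ(t) = −C t e^(−t²/2)

with the order-1 Derivative-of-Gaussian wavelet is, up to a constant, a
Gaussian-smoothed first derivative of `v`. One differentiation therefore
recovers a smoothed acceleration whose local **minima** are the initial
contacts; applying the same differentiation again yields a smoothed jerk
whose local **maxima** are the final contacts. The scale `a` (in samples)
sets the smoothing width: small scales keep sharp timing but admit
noise-induced extrema (false positives), large scales suppress noise but
blur and eventually merge or displace the event-locked features. Mean
removal before integration is required; without it the gravity/offset term
dominates the integral.

### Calibration

The proportionality constant between the raw transform and the derivative
is not specified analytically anywhere; this package calibrates it exactly
by the kernel's interior response to a unit ramp,
`gain(a, fs) = −(1/fs)·Σ_k k·w_a[k]`, where `w_a[k] = ψ(k/a)/√a` is the
sampled kernel. Division by this gain makes `smoothed_derivative` return
units of signal/s exactly for any linear input, and convergent to `dy/dt`
for smooth inputs as `a → 0` (verified: monotone error decay over scales
32 → 16 → 8 → 4 for a 1 Hz sinusoid at 250 samples/s).

Wavelet conventions in this package: `ψ` has unit L2 norm and unit
Gaussian width (`σ = 1`); note that pywt/MATLAB "gaus1" uses `t·e^(−t²)`
(`σ = 1/√2`), so its scale axis is compressed by √2 relative to ours (the
cross-check test accounts for this). The kernel is truncated at ±5·a
samples, where |ψ| < 4·10⁻⁶ of its peak; boundaries use symmetric signal
extension rather than circular convolution to avoid wrap-around artifacts
near trial edges. A guard band of 3·a samples at each end is excluded from
extremum search; analysis targets the central strides, which lie well
inside it at all useful scales. Scales are accepted as positive reals
internally; the sweep uses the integer grid 1–100.

### Pseudo-frequency

`f = fs·fc/a` with `fc = 0.2`, the conventional table constant for gaus1
(e.g. scale 16 at 100 samples/s ↔ 1.25 Hz; scales 1 and 100 at
250 samples/s ↔ 50 Hz and 0.5 Hz). This deliberately differs from the
analytic spectral peak of `ψ` (1/2π ≈ 0.159); `fc` is a configurable
constant, and frequency-domain regression models are converted back to
scales through the same constant, making them sampling-rate independent.

## Matching and cost

Estimates are matched to references within ±50 ms (configurable). The
matcher solves the assignment exactly — maximum number of in-window pairs,
then minimum total |Δt|, ties to the earlier estimate — rather than a
greedy closest-first pass; on well-separated gait event trains the two are
identical, but the exact form is the one a brute-force oracle can certify
on arbitrary inputs. Unmatched estimates are false positives (whether
inside a crowded window or in no window: spurious detections must damage
precision for the sweep to penalize noisy small scales), unmatched
references false negatives. Metrics: sensitivity `TP/(TP+FN)`, precision
`TP/(TP+FP)`, their harmonic mean F1, timing RMSE over matched pairs, its
tolerance-normalized form `RMSE_N = RMSE/tol ∈ [0,1]`, and the compact
cost `T = 1 − (1 − RMSE_N)·F1 ∈ [0,1]`.

Degenerate conventions: precision 0 when nothing is estimated, F1 = 0 when
both terms vanish, and `RMSE_N := 1` (RMSE flagged NaN) when TP = 0 — so a
scale that detects nothing has `T = 1` and can never be selected as
optimal. Pooling across trials sums counts and concatenates timing
differences (ratios are never averaged per trial). The optimal scale per
event type is the argmin of `T` over the grid, ties resolving to the
smaller scale; groups where every scale has `T = 1` return an undefined
optimum.

## Step-frequency models

Step frequency is estimated from IC times as `(n−1)/(t_last − t_first)`
(every IC at a waist sensor is one step). Optimal scales — or their
pseudo-frequencies — are regressed on step frequency by ordinary least
squares (`scipy.stats.linregress`), reporting slope, intercept, pairwise
correlation and its two-sided p-value (significance level 0.05).
`adaptive_scale` evaluates the model for a measured step frequency,
converts frequency-domain predictions to scales, rounds and clamps to the
sweep range [1, 100] — supporting per-step adaptive FC detection from two
successive ICs.

## Synthetic cohort

No public dataset exists for this protocol, so the generator is a
first-class module emulating its signal class: straight walking, waist
sensor, three self-selected speeds, native 102.4 samples/s, linearly
resampled to 250 samples/s for analysis (mirroring an optical-reference
acquisition chain).

**Timeline.** Trials carry 2 central strides: 4 ICs at step boundaries
with step durations `1/SF · (1 + cv·ε)` (cv = 0.03), and 3 FCs, each
placed `(stance_fraction − 0.5)` of a stride after the preceding
contralateral IC — the end of double support. `stance_fraction = 0.62`
follows normative gait literature (stance ≈ 60–62 % of the stride) and
must exceed 0.5 for this placement rule; one stride of lead-in/lead-out
pads the events. Ground truth is recorded exactly (continuous times).

**Waveform.** A stylized template, not a biomechanical simulation: each IC
contributes a sharp Gaussian trough (depth 2.5 m/s², width 0.05·step
duration) so the smoothed acceleration has an unbiased minimum at the IC;
each FC contributes an odd-symmetric upstroke `B·τ·e^(−τ²/2)` (amplitude
1.2 m/s², width 0.12·step duration) whose derivative — hence the smoothed
jerk — peaks exactly at the FC. Widths scale with step duration, so faster
walking yields narrower, higher-frequency patterns; this single property
is what makes the optimal scale track step frequency, and it reproduces
the qualitative structure of the real analysis: a wide high-F1 scale band
for ICs, a narrow one for FCs, FC optima shifting to smaller scales at
faster speeds, and a significantly negative optimal-FC-scale vs
step-frequency correlation. White noise (SD 0.25 m/s²) and a slow sinusoidal
baseline drift (0.2 m/s², 0.05–0.25 Hz, random phase) are added on top.

**Cohort statistics.** Subject-level (speed, step frequency) pairs are
drawn per condition from a bivariate Gaussian with means/SDs
0.84±0.11, 1.14±0.15, 1.56±0.17 m/s and 1.54±0.16, 1.87±0.16,
2.29±0.17 steps/s (slow/normal/fast) and within-condition correlation
0.96; pooled across conditions the speed–SF coefficient of determination
comes out ≈ 0.97–0.99. The default design is 20 subjects × 3 conditions ×
9 trials = 540 trials. All randomness flows from one root seed through
per-trial sub-seeds, so any trial is reproducible in isolation.

**What the generator does not emulate.** Real lumbar acceleration contains
subject-specific multi-peaked waveforms, sensor tilt cross-talk, soft-tissue
resonance, asymmetry and step-to-step waveform variability. Template shape
parameters are config-exposed, and the end-to-end accuracy figures
computed on this cohort (pooled IC/FC timing RMSE at per-condition optimal
scales, typically ≈ 7–8 ms) are calibrated-simulation surrogates: they
demonstrate that the pipeline's optimization machinery works and respects
the published accuracy bounds, not that those errors would be achieved on
any particular human cohort. Absolute optimal-scale values are likewise
cohort- and convention-dependent; only their qualitative structure
transfers.

## Problem sizes and numerical choices

The full sweep (540 trials × scales 1–100 × two CWT passes) runs in well
under a minute on one CPU; kernels are cached per scale and the first
differentiation is shared between the IC and FC chains. Scales whose
10·a+1-sample support exceeds a trial's length are skipped per trial with
a logged warning (this affects only the top of the scale range for the
fastest, shortest trials, far above any optimum). Local extrema use strict
neighbor comparison with plateau-midpoint resolution and no prominence
threshold — false positives are the matching stage's job; a minimum
inter-event separation is available but off by default. Event times snap
to the analysis sample grid (no sub-sample interpolation), matching the
sample-resolution comparison the method is normally evaluated at.

## Known limitations

- The FC detector inherits the IC trough's jerk side-lobe; at far-off
  scales the merged maximum biases FC timing — which is precisely the
  scale-sensitivity phenomenon under study, but means FC accuracy figures
  are meaningful only near the optimum.
- Two central strides per trial means truncated context: the last FC-less
  stride end can produce one trailing false positive at moderate scales,
  capping per-trial FC F1 near 0.86 on the synthetic cohort.
- Left/right side attribution is out of scope (needs more than one axis).
- Only the gaus1 wavelet is implemented; the module boundary would admit
  other mother wavelets, but none are provided.
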