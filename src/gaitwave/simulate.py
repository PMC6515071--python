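"""Synthetic lumbar vertical-acceleration trials with ground-truth events.

The generator emulates straight walking recorded by a waist-worn
accelerometer at three self-selected speeds.  Each trial carries an exact
event timeline (ICs at jittered step boundaries; each FC placed a fixed
fraction of the stride after the preceding contralateral IC, i.e. at the
end of double support) and renders acceleration as a stylized per-step
template: a sharp Gaussian trough locked to each IC and a weaker
odd-symmetric upstroke locked to each FC, with widths proportional to step
duration so that faster walking produces narrower, higher-frequency
patterns.  White measurement noise and a slow baseline drift are added on
top.  Cohort sampling couples subject-level gait speed and step frequency
through a bivariate Gaussian with a configurable correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .events import AccelTrial, GaitEvents
from .signal import Signal

__all__ = [
    "CONDITION_DEFAULTS",
    "GaitParams",
    "SyntheticTrial",
    "generate_trial",
    "generate_cohort",
]

#: Per-condition cohort statistics: mean/SD of gait speed (m/s) and of
#: step frequency (steps/s) for self-selected slow, normal and fast walking
#: in young adults.
CONDITION_DEFAULTS = {
    "slow": {"speed_mean": 0.84, "speed_sd": 0.11, "sf_mean": 1.54, "sf_sd": 0.16},
    "normal": {"speed_mean": 1.14, "speed_sd": 0.15, "sf_mean": 1.87, "sf_sd": 0.16},
    "fast": {"speed_mean": 1.56, "speed_sd": 0.17, "sf_mean": 2.29, "sf_sd": 0.17},
}


@dataclass(frozen=True)
class GaitParams:
    """Generator parameters for one walking condition.

    Timeline parameters
    -------------------
    sf_mean, sf_sd : steps/s — cohort mean and between-subject SD of step
        frequency; speed_mean, speed_sd likewise for gait speed (m/s).
    speed_sf_coupling : correlation between subject-level speed and step
        frequency deviations.
    stance_fraction : fraction of the stride spent in stance; each FC falls
        (stance_fraction - 0.5) of a stride after the preceding
        contralateral IC (the double-support offset).  Must exceed 0.5.
    step_time_cv : within-trial coefficient of variation of step duration.
    n_strides : central strides per trial (2 -> 4 ICs and 3 FCs).
    fs : native sampling rate, samples/s.

    Waveform parameters
    -------------------
    ic_amp, fc_amp : m/s**2 — depth of the IC trough and slope amplitude of
        the FC upstroke; ic_width_frac, fc_width_frac — template widths as
        fractions of the step duration; noise_sd — white noise SD (m/s**2);
        drift_amp / drift_band — amplitude and frequency band of the slow
        baseline drift.
    """

    speed_mean: float = 1.14
    speed_sd: float = 0.15
    sf_mean: float = 1.87
    sf_sd: float = 0.16
    speed_sf_coupling: float = 0.96
    stance_fraction: float = 0.62
    step_time_cv: float = 0.03
    n_strides: int = 2
    fs: float = 102.4
    ic_amp: float = 2.5
    ic_width_frac: float = 0.05
    fc_amp: float = 1.2
    fc_width_frac: float = 0.12
    noise_sd: float = 0.25
    drift_amp: float = 0.2
    drift_band: tuple = (0.05, 0.25)

    def __post_init__(self) -> None:
        if not 0.5 < self.stance_fraction < 1.0:
            raise ValueError(
                "stance_fraction must lie in (0.5, 1) for the FC placement rule "
                f"(got {self.stance_fraction!r})"
            )
        if min(self.speed_sd, self.sf_sd, self.step_time_cv, self.noise_sd) < 0:
            raise ValueError("spreads (SDs, cv) must be non-negative")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")

    @classmethod
    def for_condition(cls, condition: str, **overrides) -> "GaitParams":
        """Defaults for one of the named conditions (slow/normal/fast)."""
        if condition not in CONDITION_DEFAULTS:
            raise ValueError(f"unknown condition {condition!r}")
        kw = dict(CONDITION_DEFAULTS[condition])
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class SyntheticTrial:
    """A generated trial plus its exact ground truth and nominal gait state."""

    trial: AccelTrial
    truth: GaitEvents
    nominal_speed: float
    nominal_sf: float
    seed: int


def _event_timeline(params: GaitParams, sf: float, rng: np.random.Generator):
    """IC/FC times (s) for ``n_strides`` central strides at step frequency sf."""
    n_ic = 2 * params.n_strides
    step_nominal = 1.0 / sf
    steps = step_nominal * (1.0 + params.step_time_cv * rng.standard_normal(n_ic - 1))
    if np.any(steps <= 0):
        raise ValueError("step_time_cv too large: non-positive step duration drawn")
    lead = 2.0 * step_nominal  # one stride of lead-in / lead-out
    ics = lead + np.concatenate([[0.0], np.cumsum(steps)])
    # FC_i sits (stance_fraction - 0.5) of a stride after IC_i; the local
    # stride duration spans IC_i -> IC_(i+2), approximated by two steps.
    strides = np.empty(n_ic - 1)
    strides[:-1] = steps[:-1] + steps[1:]
    strides[-1] = steps[-1] + step_nominal
    fcs = ics[:-1] + (params.stance_fraction - 0.5) * strides
    return ics, fcs, lead


def generate_trial(
    params: GaitParams,
    subject_offset: tuple = (0.0, 0.0),
    seed: int = 0,
) -> SyntheticTrial:
    """Render one trial of vertical acceleration with exact ground truth.

    ``subject_offset`` is the (speed, step-frequency) deviation of this
    subject from the condition means; all within-trial randomness (step
    jitter, noise, drift phase) flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    speed = params.speed_mean + subject_offset[0]
    sf = params.sf_mean + subject_offset[1]
    if sf <= 0:
        raise ValueError(f"nominal step frequency must be positive, got {sf!r}")

    ics, fcs, lead = _event_timeline(params, sf, rng)
    duration = ics[-1] + lead
    n = int(round(duration * params.fs)) + 1
    t = np.arange(n) / params.fs

    step = 1.0 / sf
    u = params.ic_width_frac * step
    w = params.fc_width_frac * step
    accel = np.zeros(n)
    for ic in ics:
        accel -= params.ic_amp * np.exp(-0.5 * ((t - ic) / u) ** 2)
    for fc in fcs:
        tau = (t - fc) / w
        accel += params.fc_amp * tau * np.exp(-0.5 * tau * tau)
    if params.noise_sd > 0:
        accel += params.noise_sd * rng.standard_normal(n)
    if params.drift_amp > 0:
        f_d = rng.uniform(*params.drift_band)
        accel += params.drift_amp * np.sin(2 * np.pi * f_d * t + rng.uniform(0, 2 * np.pi))

    trial = AccelTrial(accel=Signal(accel, params.fs))
    truth = GaitEvents(ic_times=ics, fc_times=fcs, source="reference")
    return SyntheticTrial(
        trial=trial, truth=truth, nominal_speed=speed, nominal_sf=sf, seed=int(seed)
    )


def generate_cohort(
    n_subjects: int = 20,
    conditions: tuple = ("slow", "normal", "fast"),
    trials_per_condition: int = 9,
    seed: int = 0,
    params: dict | None = None,
) -> list[SyntheticTrial]:
    """Generate a full cohort of trials, deterministic per seed.

    For each subject and condition a (speed, step frequency) pair is drawn
    from a bivariate Gaussian with the configured coupling; every trial of
    that cell shares the pair and gets its own sub-seed.  ``params`` may
    map condition names to :class:`GaitParams` overrides.

    The defaults (20 subjects x 3 conditions x 9 analyzable repetitions)
    yield 540 trials.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or {}
    cond_params = {
        c: params.get(c) or GaitParams.for_condition(c) for c in conditions
    }
    root = np.random.default_rng(seed)
    trials: list[SyntheticTrial] = []
    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        for cond in conditions:
            p = cond_params[cond]
            z1, z2 = root.standard_normal(2)
            rho = p.speed_sf_coupling
            d_speed = p.speed_sd * z1
            d_sf = p.sf_sd * (rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * z2)
            for r in range(trials_per_condition):
                sub_seed = int(root.integers(0, 2**31 - 1))
                st = generate_trial(p, (d_speed, d_sf), sub_seed)
                trial = AccelTrial(
                    accel=st.trial.accel,
                    subject_id=subject_id,
                    condition=cond,
                    trial_id=f"T{r + 1:02d}",
                )
                trials.append(replace(st, trial=trial))
    return trials
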