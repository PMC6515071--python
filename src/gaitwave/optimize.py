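"""Wavelet-scale sweep, optimal-scale selection and step-frequency models.

For every candidate scale the detector is run on every trial, estimates are
matched to the reference events, and the matches are pooled within a
grouping (by default subject x condition) into per-scale performance
metrics.  The optimal scale per event type is the one minimizing the
compact cost T.  Optimal scales (or their pseudo-frequencies) are then
regressed on step frequency, and the fitted model supports adaptive,
step-by-step scale selection from two successive initial contacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cwt import (
    DEFAULT_CENTER_FREQUENCY,
    frequency_to_scale,
    scale_to_frequency,
    smoothed_derivative,
)
from .events import AccelTrial, GaitEvents, candidate_events, preprocess
from .metrics import (
    DEFAULT_TOLERANCE,
    MatchResult,
    ScaleMetrics,
    compute_metrics,
    match_events,
    metrics_row,
    pool_matches,
)

__all__ = [
    "SweepResult",
    "OptimalScale",
    "RegressionModel",
    "sweep",
    "sweep_matches",
    "pool_sweep",
    "find_optimal_scale",
    "optima_table",
    "sweep_table",
    "step_frequency",
    "group_step_frequencies",
    "fit_regression",
    "adaptive_scale",
]

logger = logging.getLogger("gaitwave")

DEFAULT_SCALES = tuple(range(1, 101))


@dataclass(frozen=True)
class SweepResult:
    """Per-scale pooled matches and metrics for one group of trials.

    ``None`` entries mark scales skipped because every trial in the group
    was too short for the wavelet support.
    """

    group: tuple
    scales: np.ndarray
    matches_ic: list
    matches_fc: list
    metrics_ic: list
    metrics_fc: list
    fs: float

    def t_costs(self, event_type: str) -> np.ndarray:
        """Cost T per scale (NaN for skipped scales)."""
        metrics = self.metrics_ic if event_type == "IC" else self.metrics_fc
        return np.array([m.t_cost if m is not None else np.nan for m in metrics])


@dataclass(frozen=True)
class OptimalScale:
    """Argmin-of-T scales per event type; ``None`` when nothing was ever
    detected (all T = 1) so no optimum exists."""

    group: tuple
    scale_opt_ic: int | None
    scale_opt_fc: int | None
    f_opt_ic: float | None
    f_opt_fc: float | None
    t_min_ic: float | None
    t_min_fc: float | None


@dataclass(frozen=True)
class RegressionModel:
    """OLS fit of optimal scale (or pseudo-frequency) on step frequency."""

    slope: float
    intercept: float
    response_kind: str  # "scale" | "frequency"
    event_type: str  # "IC" | "FC"
    r: float
    p_value: float
    stderr: float = float("nan")

    def predict(self, sf: float) -> float:
        return self.slope * sf + self.intercept


def _detect_both(v, scale: float):
    """IC minima and FC maxima from a preprocessed (integrated) trace,
    sharing the first differentiation between the two chains."""
    d1 = smoothed_derivative(v, scale)
    ic = candidate_events(d1, scale, "min")
    d2 = smoothed_derivative(d1, scale)
    fc = candidate_events(d2, scale, "max")
    return ic, fc


def sweep_matches(
    trials: Sequence[AccelTrial],
    refs: Sequence[GaitEvents],
    scales: Iterable[int] = DEFAULT_SCALES,
    tolerance: float = DEFAULT_TOLERANCE,
    axis_sign: float = 1.0,
) -> list[dict]:
    """Per-trial, per-scale match results against the reference events.

    Returns one dict per trial mapping scale -> (MatchResult_IC,
    MatchResult_FC).  Scales whose wavelet support exceeds a trial's length
    are skipped for that trial with a logged warning.
    """
    if len(trials) != len(refs):
        raise ValueError("need exactly one reference event set per trial")
    scales = list(scales)
    out: list[dict] = []
    n_skipped = 0
    for trial, ref in zip(trials, refs):
        v = preprocess(trial, axis_sign)
        per_scale: dict = {}
        for a in scales:
            try:
                ic_est, fc_est = _detect_both(v, a)
            except ValueError:
                n_skipped += 1
                continue
            per_scale[a] = (
                match_events(ic_est, ref.ic_times, tolerance),
                match_events(fc_est, ref.fc_times, tolerance),
            )
        out.append(per_scale)
    if n_skipped:
        logger.warning(
            "skipped %d (trial, scale) cells: trial too short for wavelet support",
            n_skipped,
        )
    return out


def _group_key(trial: AccelTrial, by: Sequence[str]) -> tuple:
    fields = {"subject": trial.subject_id, "condition": trial.condition, "trial": trial.trial_id}
    try:
        return tuple(fields[k] for k in by)
    except KeyError as e:
        raise ValueError(f"unknown grouping key {e.args[0]!r}") from None


def pool_sweep(
    per_trial: Sequence[dict],
    trials: Sequence[AccelTrial],
    scales: Iterable[int] = DEFAULT_SCALES,
    by: Sequence[str] = ("subject", "condition"),
    fs: float | None = None,
) -> dict:
    """Pool per-trial matches into per-group :class:`SweepResult` objects."""
    scales = np.asarray(list(scales), dtype=int)
    if scales.size == 0 or np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be a non-empty strictly increasing grid")
    fs = fs if fs is not None else trials[0].accel.fs
    groups: dict = {}
    for per_scale, trial in zip(per_trial, trials):
        groups.setdefault(_group_key(trial, by), []).append(per_scale)
    out: dict = {}
    for key, cells in groups.items():
        m_ic, m_fc, s_ic, s_fc = [], [], [], []
        for a in scales:
            pair = [c[a] for c in cells if a in c]
            if not pair:
                m_ic.append(None), m_fc.append(None)
                s_ic.append(None), s_fc.append(None)
                continue
            pooled_ic = pool_matches(p[0] for p in pair)
            pooled_fc = pool_matches(p[1] for p in pair)
            m_ic.append(pooled_ic), m_fc.append(pooled_fc)
            s_ic.append(compute_metrics(pooled_ic)), s_fc.append(compute_metrics(pooled_fc))
        out[key] = SweepResult(
            group=key, scales=scales, matches_ic=m_ic, matches_fc=m_fc,
            metrics_ic=s_ic, metrics_fc=s_fc, fs=fs,
        )
    return out


def sweep(
    trials: Sequence[AccelTrial],
    refs: Sequence[GaitEvents],
    scales: Iterable[int] = DEFAULT_SCALES,
    tolerance: float = DEFAULT_TOLERANCE,
    by: Sequence[str] = ("subject", "condition"),
    axis_sign: float = 1.0,
) -> dict:
    """Full metric sweep: detect at every scale, match, pool per group.

    Deterministic given its inputs.  Returns ``{group_key: SweepResult}``.
    """
    scales = list(scales)
    per_trial = sweep_matches(trials, refs, scales, tolerance, axis_sign)
    return pool_sweep(per_trial, trials, scales, by)


def find_optimal_scale(sw: SweepResult) -> OptimalScale:
    """Scale minimizing T per event type; ties go to the smallest scale."""
    picks = {}
    for ev in ("IC", "FC"):
        t = sw.t_costs(ev)
        if np.all(np.isnan(t)) or np.nanmin(t) >= 1.0:
            picks[ev] = (None, None, None)
            continue
        i = int(np.nanargmin(t))  # first index wins on ties: smallest scale
        a = int(sw.scales[i])
        picks[ev] = (a, scale_to_frequency(a, sw.fs), float(t[i]))
    return OptimalScale(
        group=sw.group,
        scale_opt_ic=picks["IC"][0], f_opt_ic=picks["IC"][1], t_min_ic=picks["IC"][2],
        scale_opt_fc=picks["FC"][0], f_opt_fc=picks["FC"][1], t_min_fc=picks["FC"][2],
    )


def sweep_table(sweeps: Mapping[tuple, SweepResult], by: Sequence[str]) -> pd.DataFrame:
    """Long-format per-scale metrics table across all groups."""
    rows = []
    for key, sw in sweeps.items():
        base = dict(zip(by, key))
        for i, a in enumerate(sw.scales):
            for ev, matches, metrics in (
                ("IC", sw.matches_ic, sw.metrics_ic),
                ("FC", sw.matches_fc, sw.metrics_fc),
            ):
                if matches[i] is None:
                    continue
                rows.append({**base, **metrics_row(int(a), ev, matches[i], metrics[i])})
    return pd.DataFrame(rows)


def optima_table(sweeps: Mapping[tuple, SweepResult], by: Sequence[str]) -> pd.DataFrame:
    """Optimal-scale table (one row per group and event type)."""
    rows = []
    for key, sw in sweeps.items():
        opt = find_optimal_scale(sw)
        base = dict(zip(by, key))
        for ev, a, f, t in (
            ("IC", opt.scale_opt_ic, opt.f_opt_ic, opt.t_min_ic),
            ("FC", opt.scale_opt_fc, opt.f_opt_fc, opt.t_min_fc),
        ):
            rows.append({**base, "event_type": ev, "scale_opt": a, "f_opt_hz": f, "t_min": t})
    return pd.DataFrame(rows)


def step_frequency(ic_times: Sequence[float]) -> float:
    """Step frequency (steps/s) from IC times: (n - 1) / (last - first).

    Every IC at a waist sensor is one step.  Returns NaN (undefined) with
    fewer than two ICs.
    """
    t = np.asarray(ic_times, dtype=float)
    if t.size < 2:
        return float("nan")
    span = t[-1] - t[0]
    if span <= 0:
        raise ValueError("ic_times must be strictly increasing")
    return (t.size - 1) / span


def group_step_frequencies(
    trials: Sequence[AccelTrial],
    refs: Sequence[GaitEvents],
    by: Sequence[str] = ("subject", "condition"),
) -> dict:
    """Mean per-group step frequency computed from reference IC trains."""
    acc: dict = {}
    for trial, ref in zip(trials, refs):
        acc.setdefault(_group_key(trial, by), []).append(step_frequency(ref.ic_times))
    return {k: float(np.nanmean(v)) for k, v in acc.items()}


def fit_regression(
    points: Sequence[tuple],
    response_kind: str = "scale",
    event_type: str = "IC",
) -> RegressionModel:
    """OLS of the response (optimal scale or pseudo-frequency) on SF.

    Also reports the pairwise linear correlation and its two-sided p-value.
    Requires at least 3 points with non-degenerate SF spread.
    """
    if response_kind not in ("scale", "frequency"):
        raise ValueError(f"unknown response_kind {response_kind!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (SF, response) pairs")
    sf, y = pts[:, 0], pts[:, 1]
    if np.ptp(sf) <= 0:
        raise ValueError("step-frequency values are degenerate (no spread)")
    fit = stats.linregress(sf, y)
    return RegressionModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        response_kind=response_kind,
        event_type=event_type,
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
    )


def adaptive_scale(
    sf: float,
    model: RegressionModel,
    fs: float,
    fc: float = DEFAULT_CENTER_FREQUENCY,
    scale_range: tuple = (1, 100),
) -> int:
    """Scale for the next step, from the measured step frequency.

    Evaluates the fitted model (converting pseudo-frequency to scale when
    needed), rounds to the nearest integer and clamps to ``scale_range``;
    extreme or non-physical predictions are absorbed by the clamp.
    """
    if not sf > 0:
        raise ValueError(f"step frequency must be positive, got {sf!r}")
    lo, hi = scale_range
    if model.response_kind == "frequency":
        f = model.predict(sf)
        a = frequency_to_scale(f, fs, fc) if f > 0 else float(hi)
    else:
        a = model.predict(sf)
    return int(min(max(round(a), lo), hi))
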