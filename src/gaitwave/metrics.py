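"""Tolerance-window event matching and detection performance metrics.

Estimated events are matched to reference events within a +-tolerance
window (50 ms by default).  Matched pairs are true positives with a signed
timing difference; surplus estimates are false positives and unmatched
references false negatives.  From the counts come sensitivity, precision
and F1; from the timing differences the RMSE and its tolerance-normalized
form RMSE_N; and the two combine into a compact cost

    T = 1 - (1 - RMSE_N) * F1,

which is 0 for perfect detection with perfect timing and 1 when nothing is
detected, and is the quantity minimized during scale selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DEFAULT_TOLERANCE",
    "MatchResult",
    "ScaleMetrics",
    "match_events",
    "pool_matches",
    "compute_metrics",
    "cost_T",
    "metrics_row",
]

#: Matching tolerance in seconds; slightly above typical reported mean
#: absolute timing errors of waist-sensor event detection.
DEFAULT_TOLERANCE = 0.050


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one estimated event list against a reference."""

    tp: int
    fp: int
    fn: int
    diffs: np.ndarray  # signed seconds, estimated - reference, one per TP
    tolerance: float

    def __post_init__(self) -> None:
        diffs = np.asarray(self.diffs, dtype=float)
        object.__setattr__(self, "diffs", diffs)
        if self.tp != diffs.size:
            raise ValueError("tp must equal the number of recorded differences")
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if diffs.size and np.max(np.abs(diffs)) > self.tolerance + 1e-12:
            raise ValueError("every matched difference must lie within the tolerance")


@dataclass(frozen=True)
class ScaleMetrics:
    """Performance summary at one wavelet scale.

    ``rmse`` is NaN (flagged undefined) when there are no true positives;
    ``rmse_n`` is then set to 1 so that the cost T saturates at 1 and a
    scale detecting nothing can never be selected as optimal.
    """

    sensitivity: float
    precision: float
    f1: float
    rmse: float  # seconds; NaN when tp == 0
    rmse_n: float
    t_cost: float


def match_events(
    est: Sequence[float],
    ref: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
) -> MatchResult:
    """Match estimated to reference events within ``+-tolerance`` seconds.

    Pairings are chosen to maximize the number of matches and, among
    maximum-cardinality pairings, minimize the total absolute timing
    difference; equidistant alternatives resolve to the earlier estimate.
    Each estimate participates at most once.  Estimates left unmatched
    (extra events inside a window, or events in no window at all) count as
    false positives; references with no in-window estimate as false
    negatives.

    Raises
    ------
    ValueError
        If either list is unsorted or the tolerance is not positive.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if not tolerance > 0:
        raise ValueError(f"tolerance must be positive, got {tolerance!r}")
    for name, arr in (("est", est), ("ref", ref)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} event times must be sorted ascending")

    if est.size == 0 or ref.size == 0:
        return MatchResult(0, int(est.size), int(ref.size), np.empty(0), tolerance)

    signed = est[None, :] - ref[:, None]  # (n_ref, n_est)
    absd = np.abs(signed)
    feasible = absd <= tolerance
    # big-M on infeasible pairs makes the assignment prefer any solution
    # with more in-window matches; the tiny per-column epsilon breaks
    # exact-distance ties toward the earlier estimate.
    big = 10.0 * tolerance * (max(est.size, ref.size) + 1)
    cost = np.where(feasible, absd, big)
    cost = cost + np.arange(est.size)[None, :] * (tolerance * 1e-9)
    rows, cols = linear_sum_assignment(cost)
    ok = feasible[rows, cols]
    rows, cols = rows[ok], cols[ok]
    order = np.argsort(rows)
    diffs = signed[rows[order], cols[order]]
    tp = int(rows.size)
    return MatchResult(tp, int(est.size) - tp, int(ref.size) - tp, diffs, tolerance)


def pool_matches(matches: Iterable[MatchResult]) -> MatchResult:
    """Pool matches across trials: sum counts, concatenate differences.

    Pooling happens at the count level (not by averaging per-trial ratios),
    so short trials do not get disproportionate weight.
    """
    matches = list(matches)
    if not matches:
        raise ValueError("cannot pool an empty collection of matches")
    tol = matches[0].tolerance
    if any(abs(m.tolerance - tol) > 1e-12 for m in matches):
        raise ValueError("cannot pool matches computed at different tolerances")
    return MatchResult(
        tp=sum(m.tp for m in matches),
        fp=sum(m.fp for m in matches),
        fn=sum(m.fn for m in matches),
        diffs=np.concatenate([m.diffs for m in matches]) if matches else np.empty(0),
        tolerance=tol,
    )


def cost_T(rmse_n: float, f1: float) -> float:
    """Compact detection cost: ``1 - (1 - rmse_n) * f1``, in [0, 1]."""
    if not (0.0 <= rmse_n <= 1.0 and 0.0 <= f1 <= 1.0):
        raise ValueError("rmse_n and f1 must both lie in [0, 1]")
    return 1.0 - (1.0 - rmse_n) * f1


def compute_metrics(match: MatchResult) -> ScaleMetrics:
    """All six performance quantities for one match result.

    Degenerate cases follow fixed conventions rather than raising:
    precision is 0 when nothing was estimated, sensitivity 0 when there is
    nothing to find, F1 is 0 when both are 0, and with no true positives
    RMSE is flagged NaN with RMSE_N = 1 (forcing T = 1).
    """
    n_ref = match.tp + match.fn
    n_est = match.tp + match.fp
    sensitivity = match.tp / n_ref if n_ref else 0.0
    precision = match.tp / n_est if n_est else 0.0
    denom = sensitivity + precision
    f1 = 2.0 * sensitivity * precision / denom if denom else 0.0
    if match.tp:
        rmse = float(np.sqrt(np.mean(match.diffs**2)))
        rmse_n = min(rmse / match.tolerance, 1.0)
    else:
        rmse = float("nan")
        rmse_n = 1.0
    return ScaleMetrics(
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        rmse=rmse,
        rmse_n=rmse_n,
        t_cost=cost_T(rmse_n, f1),
    )


def metrics_row(scale: int, event_type: str, match: MatchResult, metrics: ScaleMetrics) -> dict:
    """One row of the per-scale metrics table (TSV schema)."""
    return {
        "scale": scale,
        "event_type": event_type,
        "tp": match.tp,
        "fp": match.fp,
        "fn": match.fn,
        "sensitivity": metrics.sensitivity,
        "precision": metrics.precision,
        "f1": metrics.f1,
        "rmse_s": metrics.rmse,
        "rmse_n": metrics.rmse_n,
        "t_cost": metrics.t_cost,
    }
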