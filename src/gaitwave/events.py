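"""Gait event detection from lumbar vertical acceleration.

The detection chain integrates the (mean-removed) vertical acceleration and
then differentiates it with the gaus1 CWT: one differentiation recovers a
Gaussian-smoothed acceleration whose local minima mark initial contacts
(IC, heel strike); a second differentiation yields a smoothed jerk whose
local maxima mark final contacts (FC, toe off).  The wavelet scale controls
the amount of smoothing and is the tunable parameter the rest of the
package optimizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .cwt import smoothed_derivative
from .signal import Signal

__all__ = [
    "AccelTrial",
    "GaitEvents",
    "preprocess",
    "detect_ic",
    "detect_fc",
    "detect",
    "candidate_events",
]

#: Samples excluded from extremum search at each end, in units of scale.
#: Edge transients of the symmetric-padded CWT live within a few scale
#: lengths of the boundary; analysis targets the central strides anyway.
GUARD_FACTOR = 3


@dataclass(frozen=True)
class AccelTrial:
    """One walking trial of vertical acceleration at the waist.

    ``accel`` holds vertical acceleration in m/s**2 with the axis sign such
    that ICs appear as minima of the smoothed acceleration (sensors mounted
    with the opposite axis convention need ``axis_sign=-1`` at load time or
    in the detector calls).
    """

    accel: Signal
    subject_id: str = ""
    condition: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.accel.duration < 1.0:
            raise ValueError(
                f"trial must span at least 1 s, got {self.accel.duration:.3f} s"
            )


@dataclass(frozen=True)
class GaitEvents:
    """Ordered IC and FC event times (seconds) for one trial."""

    ic_times: np.ndarray
    fc_times: np.ndarray
    source: str = "estimated"

    def __post_init__(self) -> None:
        for name in ("ic_times", "fc_times"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, t)
        if self.source not in ("estimated", "reference"):
            raise ValueError(f"unknown event source {self.source!r}")

    @property
    def n_ic(self) -> int:
        return self.ic_times.size

    @property
    def n_fc(self) -> int:
        return self.fc_times.size


def preprocess(trial: AccelTrial, axis_sign: float = 1.0) -> Signal:
    """Mean-remove and time-integrate the vertical acceleration.

    Returns the cumulative trapezoidal integral of the mean-removed (and
    optionally sign-flipped) acceleration: a velocity-like trace of the same
    length and sampling rate.  Mean removal keeps the integral from being
    dominated by gravity/offset drift.
    """
    x = axis_sign * (trial.accel.samples - trial.accel.samples.mean())
    v = cumulative_trapezoid(x, dx=1.0 / trial.accel.fs, initial=0.0)
    return Signal(v, trial.accel.fs, trial.accel.t0)


def _local_extrema(x: np.ndarray, kind: str) -> np.ndarray:
    """Indices of local minima or maxima with plateau-midpoint resolution.

    A run of equal values bounded by a descending and an ascending segment
    is a single minimum at the (floor) midpoint of the flat run, and
    symmetrically for maxima.  Monotone or constant signals yield none.
    """
    d = np.sign(np.diff(x))
    nz = np.nonzero(d)[0]
    if nz.size < 2:
        return np.array([], dtype=int)
    s = d[nz]
    want = (-1.0, 1.0) if kind == "min" else (1.0, -1.0)
    j = np.nonzero((s[:-1] == want[0]) & (s[1:] == want[1]))[0]
    # extremum plateau spans samples nz[j]+1 .. nz[j+1]; midpoint resolves it
    return (nz[j] + 1 + nz[j + 1]) // 2


def candidate_events(
    sig: Signal, scale: float, kind: str, min_separation: float = 0.0
) -> np.ndarray:
    """Times of local extrema of ``sig`` outside the boundary guard band.

    ``kind`` is ``"min"`` or ``"max"``.  The guard band of
    ``GUARD_FACTOR * scale`` samples at each end excludes CWT edge
    transients.  ``min_separation`` (seconds, 0 = off) optionally drops any
    candidate closer than that to the previously kept one.
    """
    idx = _local_extrema(sig.samples, kind)
    guard = GUARD_FACTOR * int(math.ceil(scale))
    idx = idx[(idx >= guard) & (idx <= len(sig) - 1 - guard)]
    times = sig.t0 + idx / sig.fs
    if min_separation > 0 and times.size > 1:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= min_separation:
                kept.append(t)
        times = np.asarray(kept)
    return times


def detect_ic(
    trial: AccelTrial,
    scale: float,
    axis_sign: float = 1.0,
    min_separation: float = 0.0,
) -> np.ndarray:
    """Initial-contact times: minima of the once-differentiated integral.

    Integrate the mean-removed acceleration, CWT-differentiate at ``scale``
    (recovering a smoothed acceleration) and return the times of all local
    minima outside the guard band, sorted ascending.  A constant trial
    yields an empty array.
    """
    v = preprocess(trial, axis_sign)
    sa = smoothed_derivative(v, scale)
    return candidate_events(sa, scale, "min", min_separation)


def detect_fc(
    trial: AccelTrial,
    scale: float,
    axis_sign: float = 1.0,
    min_separation: float = 0.0,
) -> np.ndarray:
    """Final-contact times: maxima of the twice-differentiated integral.

    Same chain as :func:`detect_ic` with a second CWT differentiation at the
    same scale (yielding a smoothed jerk) and local maxima instead of minima.
    """
    v = preprocess(trial, axis_sign)
    sj = smoothed_derivative(smoothed_derivative(v, scale), scale)
    return candidate_events(sj, scale, "max", min_separation)


def detect(
    trial: AccelTrial,
    ic_scale: float,
    fc_scale: float,
    axis_sign: float = 1.0,
    min_separation: float = 0.0,
) -> GaitEvents:
    """Run both detectors (IC and FC may use different scales)."""
    return GaitEvents(
        ic_times=detect_ic(trial, ic_scale, axis_sign, min_separation),
        fc_times=detect_fc(trial, fc_scale, axis_sign, min_separation),
        source="estimated",
    )
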