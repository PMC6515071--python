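"""Cohort-level conveniences tying generation, detection and scoring together."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .events import AccelTrial
from .metrics import DEFAULT_TOLERANCE, pool_matches
from .optimize import SweepResult, find_optimal_scale
from .signal import resample_linear
from .simulate import SyntheticTrial

__all__ = ["materialize", "pooled_rmse_at_optima"]


def materialize(
    cohort: Sequence[SyntheticTrial], fs_target: float = 250.0
) -> tuple[list[AccelTrial], list]:
    """Resample every generated trial to the analysis rate.

    Returns parallel lists of resampled :class:`AccelTrial` objects and
    their ground-truth event sets, mirroring an acquisition chain that
    records at the sensor's native rate and analyzes at ``fs_target``.
    """
    trials, refs = [], []
    for st in cohort:
        sig = resample_linear(st.trial.accel, fs_target)
        trials.append(
            AccelTrial(
                accel=sig,
                subject_id=st.trial.subject_id,
                condition=st.trial.condition,
                trial_id=st.trial.trial_id,
            )
        )
        refs.append(st.truth)
    return trials, refs


def pooled_rmse_at_optima(sweeps: Mapping[tuple, SweepResult]) -> dict:
    """Pooled timing RMSE (seconds) at each group's optimal scale.

    For each group the optimal scale per event type is selected by minimum
    cost T; the matched timing differences at those scales are pooled
    across groups and summarized as one RMSE per event type.  Groups with
    no defined optimum contribute nothing.
    """
    out = {}
    for ev in ("IC", "FC"):
        pooled = []
        for sw in sweeps.values():
            opt = find_optimal_scale(sw)
            a = opt.scale_opt_ic if ev == "IC" else opt.scale_opt_fc
            if a is None:
                continue
            i = int(np.where(sw.scales == a)[0][0])
            match = sw.matches_ic[i] if ev == "IC" else sw.matches_fc[i]
            pooled.append(match)
        if not pooled:
            out[ev] = float("nan")
            continue
        allm = pool_matches(pooled)
        out[ev] = float(np.sqrt(np.mean(allm.diffs**2))) if allm.tp else float("nan")
    return out
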