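"""Scale sweep, optimum selection, step-frequency regression, adaptive scale."""

import numpy as np
import pytest

from gaitwave import (
    adaptive_scale,
    find_optimal_scale,
    fit_regression,
    step_frequency,
    sweep,
)
from gaitwave.metrics import MatchResult, compute_metrics
from gaitwave.optimize import (
    RegressionModel,
    SweepResult,
    group_step_frequencies,
    pool_sweep,
    sweep_matches,
)


def make_sweep_result(t_ic, t_fc=None, scales=None, fs=250.0):
    """SweepResult with synthetic T curves (metrics built to produce them)."""
    t_fc = t_fc if t_fc is not None else t_ic
    scales = np.asarray(scales if scales is not None else range(1, len(t_ic) + 1))

    def metrics_for(t):
        out = []
        for ti in t:
            if np.isnan(ti):
                out.append(None)
            elif ti >= 1.0:
                out.append(compute_metrics(MatchResult(0, 0, 1, np.empty(0), 0.05)))
            else:
                # f1 = 1, rmse_n = ti reproduces T = ti
                d = 0.05 * ti
                out.append(compute_metrics(MatchResult(1, 0, 0, np.array([d]), 0.05)))
        return out

    return SweepResult(
        group=("test",), scales=scales,
        matches_ic=[None] * len(scales), matches_fc=[None] * len(scales),
        metrics_ic=metrics_for(t_ic), metrics_fc=metrics_for(t_fc), fs=fs,
    )


class TestFindOptimalScale:
    def test_unique_minimum(self):
        t = np.ones(40)
        t[25] = 0.2  # scale 26
        opt = find_optimal_scale(make_sweep_result(t))
        assert opt.scale_opt_ic == 26
        assert opt.t_min_ic == pytest.approx(0.2)
        assert opt.f_opt_ic == pytest.approx(250.0 * 0.2 / 26)

    def test_tie_breaks_to_smaller_scale(self):
        t = np.ones(40)
        t[24] = t[25] = 0.3
        opt = find_optimal_scale(make_sweep_result(t))
        assert opt.scale_opt_ic == 25

    def test_all_ones_is_undefined(self):
        opt = find_optimal_scale(make_sweep_result(np.ones(10)))
        assert opt.scale_opt_ic is None and opt.t_min_ic is None

    def test_skipped_scales_ignored(self):
        t = np.array([np.nan, 0.4, 0.2, np.nan])
        opt = find_optimal_scale(make_sweep_result(t))
        assert opt.scale_opt_ic == 3


class TestSweep:
    def test_self_match_is_perfect_at_every_scale(self, mini_cohort):
        """Reference fed as its own estimate: f1 = 1 and T = rmse_n = 0."""
        from gaitwave.metrics import match_events

        _, trials, refs = mini_cohort
        ref = refs[0]
        m = match_events(ref.ic_times, ref.ic_times, 0.05)
        s = compute_metrics(m)
        assert s.f1 == 1.0 and s.t_cost == s.rmse_n == 0.0

    def test_deterministic_and_reproducible(self, mini_cohort):
        _, trials, refs = mini_cohort
        a = sweep(trials[:3], refs[:3], scales=[20, 40], by=("trial",))
        b = sweep(trials[:3], refs[:3], scales=[20, 40], by=("trial",))
        for key in a:
            for i in range(2):
                assert a[key].matches_ic[i].tp == b[key].matches_ic[i].tp
                np.testing.assert_array_equal(
                    a[key].matches_ic[i].diffs, b[key].matches_ic[i].diffs
                )
                assert a[key].metrics_fc[i].t_cost == b[key].metrics_fc[i].t_cost

    def test_ic_f1_band_wider_than_fc(self, mini_cohort):
        _, trials, refs = mini_cohort
        sweeps = sweep(trials, refs, by=("condition",))
        for key, sw in sweeps.items():
            def longest_band(metrics):
                best = cur = 0
                for m in metrics:
                    cur = cur + 1 if (m is not None and m.f1 > 0.9) else 0
                    best = max(best, cur)
                return best

            assert longest_band(sw.metrics_ic) > longest_band(sw.metrics_fc)

    def test_too_short_trial_cells_skipped_not_fatal(self, mini_cohort, caplog):
        _, trials, refs = mini_cohort
        short = [t for t in trials if len(t.accel) < 1001]
        assert short, "expected at least one trial shorter than the scale-100 support"
        res = sweep(short[:1], refs[:1], scales=[10, 100], by=("trial",))
        sw = next(iter(res.values()))
        assert sw.metrics_ic[0] is not None and sw.metrics_ic[1] is None


class TestStepFrequency:
    def test_uniform_train(self):
        assert step_frequency([0, 0.5, 1.0, 1.5]) == pytest.approx(2.0)

    def test_irregular_train(self):
        assert step_frequency([0, 0.65, 1.30]) == pytest.approx(1.538, abs=1e-3)

    def test_single_event_undefined(self):
        assert np.isnan(step_frequency([1.0]))

    def test_group_means(self, mini_cohort):
        _, trials, refs = mini_cohort
        sfs = group_step_frequencies(trials, refs, by=("condition",))
        assert sfs[("slow",)] < sfs[("normal",)] < sfs[("fast",)]


class TestRegression:
    def test_exact_recovery_scale_model(self):
        sf = np.linspace(1.2, 2.6, 10)
        pts = list(zip(sf, -10.0 * sf + 56.0))
        m = fit_regression(pts, "scale", "IC")
        assert m.slope == pytest.approx(-10.0, abs=1e-10)
        assert m.intercept == pytest.approx(56.0, abs=1e-9)
        assert m.r == pytest.approx(-1.0, abs=1e-12)

    def test_exact_recovery_frequency_model(self):
        sf = np.linspace(1.4, 2.4, 8)
        pts = list(zip(sf, 3.6 * sf - 4.5))
        m = fit_regression(pts, "frequency", "FC")
        assert m.slope == pytest.approx(3.6, abs=1e-10)
        assert m.intercept == pytest.approx(-4.5, abs=1e-9)

    def test_noisy_recovery_within_ols_bounds(self):
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            sf = rng.uniform(1.3, 2.5, size=60)
            y = 3.6 * sf - 4.5 + rng.normal(0, 1.0, size=60)
            m = fit_regression(list(zip(sf, y)), "frequency", "FC")
            hits += abs(m.slope - 3.6) <= 3.0 * m.stderr
        assert hits / n_rep >= 0.95

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError, match="spread|degenerate"):
            fit_regression([(2.0, 1), (2.0, 2), (2.0, 3)], "scale", "IC")

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_regression([(1.0, 2.0), (2.0, 3.0)], "scale", "IC")


class TestAdaptiveScale:
    SCALE_MODEL = RegressionModel(-10.0, 56.0, "scale", "IC", -0.9, 0.01)
    FREQ_MODEL = RegressionModel(3.6, -4.5, "frequency", "FC", -0.85, 1e-10)

    def test_scale_domain_model(self):
        assert adaptive_scale(2.0, self.SCALE_MODEL, fs=250.0) == 36

    def test_clamping(self):
        assert adaptive_scale(6.0, self.SCALE_MODEL, fs=250.0) == 1

    def test_frequency_domain_model(self):
        # f = 3.6*2 - 4.5 = 2.7 Hz -> scale round(50 / 2.7) = 19
        assert adaptive_scale(2.0, self.FREQ_MODEL, fs=250.0) == 19

    def test_shift_invariance_through_step_frequency(self):
        ics = np.array([1.0, 1.52, 2.05, 2.55])
        for dt in (0.0, 3.7, -0.5):
            sf = step_frequency(ics + dt)
            assert adaptive_scale(sf, self.SCALE_MODEL, fs=250.0) == adaptive_scale(
                step_frequency(ics), self.SCALE_MODEL, fs=250.0
            )

    def test_nonpositive_sf_rejected(self):
        with pytest.raises(ValueError):
            adaptive_scale(0.0, self.SCALE_MODEL, fs=250.0)
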