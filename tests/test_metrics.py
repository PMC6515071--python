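"""Tolerance-window matching, performance metrics and the cost function."""

from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitwave import MatchResult, compute_metrics, cost_T, match_events, pool_matches


def oracle_match(est, ref, tol):
    """Exhaustive assignment: maximize TP count, then minimize total |diff|.

    Independent of the production matcher; recursion over references with a
    bitmask of used estimates.
    """
    est, ref = list(est), list(ref)

    @lru_cache(maxsize=None)
    def rec(i, used):
        if i == len(ref):
            return (0, 0.0)
        best = rec(i + 1, used)
        for j, e in enumerate(est):
            if not used >> j & 1 and abs(e - ref[i]) <= tol:
                tp, c = rec(i + 1, used | 1 << j)
                cand = (tp + 1, c + abs(e - ref[i]))
                if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                    best = cand
        return best

    tp, _ = rec(0, 0)
    rec.cache_clear()
    return tp, len(est) - tp, len(ref) - tp


sorted_times = st.lists(
    st.floats(0.0, 1.0, allow_nan=False, width=32), min_size=0, max_size=8
).map(sorted)


class TestMatching:
    def test_worked_example_two_matches(self):
        m = match_events([1.02, 2.03], [1.00, 2.00], 0.05)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)
        np.testing.assert_allclose(m.diffs, [0.02, 0.03])

    def test_no_estimates_all_missed(self):
        m = match_events([], [1.00], 0.05)
        assert (m.tp, m.fp, m.fn) == (0, 0, 1)

    def test_out_of_window_estimate_is_fp_and_fn(self):
        m = match_events([1.10], [1.00], 0.05)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_extra_in_window_estimate_is_fp(self):
        m = match_events([0.99, 1.02], [1.00], 0.05)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.diffs[0] == pytest.approx(-0.01)

    def test_crossing_configuration_matches_both(self):
        # a greedy closest-first matcher would leave one reference unmatched
        m = match_events([-0.04, 0.01], [0.0, 0.05], 0.05)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_equidistant_tie_goes_to_earlier_estimate(self):
        m = match_events([0.98, 1.02], [1.00], 0.05)
        assert m.diffs[0] == pytest.approx(-0.02)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            match_events([2.0, 1.0], [1.0], 0.05)
        with pytest.raises(ValueError, match="sorted"):
            match_events([1.0], [2.0, 1.0], 0.05)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(est=sorted_times, ref=sorted_times)
    def test_agrees_with_exhaustive_oracle(self, est, ref):
        m = match_events(est, ref, 0.05)
        assert (m.tp, m.fp, m.fn) == oracle_match(est, ref, 0.05)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(est=sorted_times, ref=sorted_times)
    def test_conservation(self, est, ref):
        m = match_events(est, ref, 0.05)
        assert m.tp + m.fn == len(ref)
        assert m.tp + m.fp == len(est)
        assert m.diffs.size == m.tp

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(est=sorted_times, ref=sorted_times, tols=st.tuples(st.floats(0.01, 0.2), st.floats(0.01, 0.2)))
    def test_tp_monotone_in_tolerance(self, est, ref, tols):
        lo, hi = sorted(tols)
        assert match_events(est, ref, hi).tp >= match_events(est, ref, lo).tp


class TestMetrics:
    def test_perfect_detection(self):
        m = MatchResult(2, 0, 0, np.array([0.02, 0.03]), 0.05)
        s = compute_metrics(m)
        assert (s.sensitivity, s.precision, s.f1) == (1.0, 1.0, 1.0)
        assert s.rmse == pytest.approx(np.sqrt((0.02**2 + 0.03**2) / 2), abs=1e-12)
        assert s.rmse == pytest.approx(0.02550, abs=5e-5)

    def test_half_and_half(self):
        s = compute_metrics(MatchResult(1, 1, 1, np.array([0.0]), 0.05))
        assert (s.sensitivity, s.precision, s.f1) == (0.5, 0.5, 0.5)

    def test_no_detection_worst_case(self):
        s = compute_metrics(MatchResult(0, 0, 2, np.empty(0), 0.05))
        assert (s.sensitivity, s.precision, s.f1) == (0.0, 0.0, 0.0)
        assert np.isnan(s.rmse) and s.rmse_n == 1.0 and s.t_cost == 1.0

    def test_rmse_n_is_rmse_over_tolerance(self):
        s = compute_metrics(MatchResult(1, 0, 0, np.array([0.03]), 0.05))
        assert s.rmse_n == pytest.approx(0.6)
        assert s.t_cost == pytest.approx(cost_T(s.rmse_n, s.f1))


class TestCost:
    @pytest.mark.parametrize(
        "rmse_n,f1,expected", [(0.0, 1.0, 0.0), (0.7, 0.0, 1.0), (0.5, 0.8, 0.6)]
    )
    def test_values(self, rmse_n, f1, expected):
        assert cost_T(rmse_n, f1) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_both_arguments(self):
        assert cost_T(0.3, 0.9) < cost_T(0.3, 0.8)  # decreasing in f1
        assert cost_T(0.4, 0.8) > cost_T(0.3, 0.8)  # increasing in rmse_n

    @pytest.mark.parametrize("bad", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.2)])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            cost_T(*bad)


class TestPooling:
    def test_counts_sum_and_diffs_concatenate(self):
        a = MatchResult(1, 0, 1, np.array([0.01]), 0.05)
        b = MatchResult(2, 1, 0, np.array([-0.02, 0.04]), 0.05)
        p = pool_matches([a, b])
        assert (p.tp, p.fp, p.fn) == (3, 1, 1)
        np.testing.assert_allclose(p.diffs, [0.01, -0.02, 0.04])

    def test_mixed_tolerances_rejected(self):
        a = MatchResult(0, 0, 0, np.empty(0), 0.05)
        b = MatchResult(0, 0, 0, np.empty(0), 0.06)
        with pytest.raises(ValueError, match="tolerance"):
            pool_matches([a, b])
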