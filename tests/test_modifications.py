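"""Transforms, rate bounds and the penalty function."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chanbench.models import RateExpression
from chanbench.modifications import (
    BoundsSpec,
    Modification,
    RATE_LOWER,
    RATE_UPPER,
    check_bounds,
    from_search_space,
    max_rate,
    penalty,
    penalty_gradient,
    rate_bounds_from_timescales,
    to_search_space,
)


def test_rate_bounds_from_timescales():
    lo, hi = rate_bounds_from_timescales()
    assert lo == pytest.approx(1.67e-5, rel=2e-3)
    assert hi == pytest.approx(1000.0)
    assert (RATE_LOWER, RATE_UPPER) == (lo, hi)


class TestMaxRate:
    def test_increasing_exponential_peaks_at_60mV(self):
        r = RateExpression("pos_exp", A=0, b=1)
        p = np.array([2.0, 0.01])
        assert max_rate(r, p) == pytest.approx(2.0 * np.exp(0.6))

    def test_decreasing_exponential_peaks_at_minus_120mV(self):
        r = RateExpression("neg_exp", A=0, b=1)
        p = np.array([2.0, 0.01])
        assert max_rate(r, p) == pytest.approx(2.0 * np.exp(1.2))

    def test_general_rate_grid_matches_finer_grid(self):
        # monotone voltage dependence: the grid maximum sits at the range
        # endpoint on any grid, so coarse and 10x-finer grids agree exactly
        r = RateExpression(
            "general",
            func=lambda p, V: p[0] / (np.exp(-(np.asarray(V, float) + 10) / 8.5)
                                      + np.exp(-(np.asarray(V, float) - 30) / 59.0)))
        p = np.array([0.65])
        assert max_rate(r, p) == pytest.approx(max_rate(r, p, n_grid=1810), rel=1e-6)
        # interior peak: the default grid resolves the maximum of a smooth
        # rate to well under the grid-spacing error bound
        bump = RateExpression(
            "general",
            func=lambda p, V: p[0] * np.exp(-((np.asarray(V, float) - 10.3) / 40) ** 2))
        assert max_rate(bump, p) == pytest.approx(max_rate(bump, p, n_grid=18100),
                                                  rel=1e-3)


class TestPenalty:
    def setup_method(self):
        self.bounds = BoundsSpec(np.array([0.0, -1.0]), np.array([1.0, 1.0]))

    def test_zero_inside(self):
        assert penalty(np.array([0.5, 0.0]), self.bounds) == 0.0

    def test_hand_evaluated_parameter_violation(self):
        # one parameter above its upper bound by e-1: 1e5*(1+ln(e)) = 2e5
        assert penalty(np.array([1.0 + (np.e - 1.0), 0.0]),
                       self.bounds) == pytest.approx(2e5)

    def test_hand_evaluated_rate_violation(self):
        rate = RateExpression("constant", A=0)
        b = BoundsSpec(np.array([-10.0]), np.array([10.0]),
                       np.array([1.0]), np.array([100.0]))
        # rate below its lower bound by e-1
        val = penalty(np.array([1.0 - (np.e - 1.0)]), b, [rate])
        assert val == pytest.approx(2e5)

    def test_boundary_counts_as_violation(self):
        # H(0) = 1: sitting exactly on a bound is penalised
        assert penalty(np.array([1.0, 0.0]), self.bounds) == pytest.approx(1e5)

    @settings(max_examples=50, deadline=None)
    @given(d1=st.floats(0.0, 1e6), d2=st.floats(0.0, 1e6))
    def test_monotone_in_violation_distance(self, d1, d2):
        lo, hi = np.array([0.0]), np.array([1.0])
        b = BoundsSpec(lo, hi)
        p_small = penalty(np.array([1.0 + min(d1, d2)]), b)
        p_large = penalty(np.array([1.0 + max(d1, d2)]), b)
        assert p_large >= p_small >= 1e5

    def test_subgradient_matches_fd_outside(self):
        p = np.array([1.5, 0.0])
        g = penalty_gradient(p, self.bounds)
        h = 1e-7
        fd = (penalty(p + [h, 0], self.bounds) - penalty(p - [h, 0], self.bounds)) / (2 * h)
        assert g[0] == pytest.approx(fd, rel=1e-5)
        assert g[1] == 0.0


class TestTransforms:
    def test_scale_transform_maps_truth_to_ones(self, fixture_problem):
        mod = Modification(scale_transform=True)
        x = to_search_space(fixture_problem.true_parameters, mod, fixture_problem)
        assert np.allclose(x, 1.0)

    def test_no_flags_is_identity(self, fixture_problem):
        mod = Modification()
        p = np.array([0.1, 0.2, 0.3])
        assert np.array_equal(to_search_space(p, mod, fixture_problem), p)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_round_trip_is_exact(self, fixture_problem, seed):
        rng = np.random.default_rng(seed)
        p = np.abs(rng.lognormal(0, 1, 3)) + 1e-6
        for mod in (Modification(log_transform=True),
                    Modification(scale_transform=True),
                    Modification(log_transform=True, scale_transform=True)):
            x = to_search_space(p, mod, fixture_problem)
            back = from_search_space(x, mod, fixture_problem)
            assert np.allclose(back, p, rtol=1e-12)

    def test_log_of_nonpositive_raises(self, fixture_problem):
        mod = Modification(log_transform=True)
        with pytest.raises(ValueError):
            to_search_space(np.array([-1.0, 0.1, 0.1]), mod, fixture_problem)


class TestCheckBounds:
    def test_true_parameters_accessible_everywhere(self):
        from chanbench.problems import build_problem

        mod = Modification(parameter_bounds=True, rate_bounds=True)
        for name in ("fixture_hh", "loewe_ikr", "moreno_ina"):
            problem = build_problem(name)
            ok, terms = check_bounds(problem.true_parameters, mod, problem)
            assert ok, (name, terms)

    def test_boundary_point_is_out_of_bounds(self, fixture_problem):
        mod = Modification(parameter_bounds=True)
        p = fixture_problem.true_parameters.copy()
        p[0] = fixture_problem.bounds.upper[0]
        ok, terms = check_bounds(p, mod, fixture_problem)
        assert not ok and terms

    def test_rate_only_violation_detected(self, fixture_problem):
        mod = Modification(rate_bounds=True)
        p = fixture_problem.true_parameters.copy()
        p[1] = fixture_problem.bounds.upper[1] * 0.999  # inside the box
        p[0] = 500.0  # opening-rate coefficient blows the rate cap
        ok, terms = check_bounds(np.array([500.0, p[1], p[2]]),
                                 Modification(rate_bounds=True), fixture_problem)
        assert not ok
        assert any(kind.startswith("rate") for _, (kind, _) in [(d, t) for d, t in terms])

    def test_in_bounds_iff_penalty_zero(self, fixture_problem, rng):
        mod = Modification(parameter_bounds=True, rate_bounds=True)
        for _ in range(20):
            p = fixture_problem.true_parameters * np.exp(rng.uniform(-3, 3, 3))
            ok, _ = check_bounds(p, mod, fixture_problem)
            pen = penalty(p, fixture_problem.bounds, fixture_problem.rate_expressions)
            assert ok == (pen == 0.0)
            if not ok:
                assert pen >= 1e5
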