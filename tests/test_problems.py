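"""Benchmark-problem behaviour: dimensions, self-consistency of data and
cost, penalty routing, sampling regions and modification invariance."""

import numpy as np
import pytest

from chanbench.modifications import Modification, from_search_space, to_search_space
from chanbench.problems import build_problem, compute_summary_statistics, generate_data
from chanbench.tracking import Tracker


@pytest.mark.parametrize("name,n_params", [
    ("staircase_hh", 9),
    ("staircase_mm", 15),
    ("loewe_ikr", 12),
    ("loewe_ikur", 25),
    ("moreno_ina", 16),
    ("fixture_hh", 3),
])
def test_problem_dimensionality(name, n_params, request):
    fixture_names = {"staircase_hh": "staircase_hh", "staircase_mm": "staircase_mm",
                     "loewe_ikr": "loewe_ikr", "loewe_ikur": "loewe_ikur",
                     "moreno_ina": "moreno_ina", "fixture_hh": "fixture_problem"}
    problem = request.getfixturevalue(fixture_names[name])
    assert problem.n_parameters == n_params
    assert problem.true_parameters.size == n_params


def test_unknown_problem_name_raises():
    with pytest.raises(KeyError):
        build_problem("no_such_problem")


class TestData:
    def test_noise_free_cost_zero_at_truth(self, loewe_ikr, loewe_ikur, moreno_ina):
        for problem in (loewe_ikr, loewe_ikur, moreno_ina):
            assert problem.cost(problem.true_parameters) < 1e-12

    def test_staircase_data_deterministic_in_seed(self):
        a = build_problem("staircase_hh")
        d1 = generate_data(a, seed=99).copy()
        d2 = generate_data(a, seed=99)
        assert np.array_equal(d1, d2)
        d3 = generate_data(a, seed=100)
        assert not np.array_equal(d1, d3)

    def test_staircase_noise_is_centred_gaussian(self, staircase_hh):
        from chanbench.solvers import solve

        clean = solve(staircase_hh.model, staircase_hh.protocols[0],
                      staircase_hh.true_parameters, method=staircase_hh.solver,
                      settings=staircase_hh.solver_settings).current
        noise = staircase_hh.data - clean
        sigma = staircase_hh.noise_sigma
        n = noise.size
        assert abs(noise.mean()) < 3 * sigma / np.sqrt(n)
        assert noise.std() == pytest.approx(sigma, rel=0.05)

    def test_cost_at_truth_below_threshold_for_all_problems(
            self, staircase_hh, staircase_mm, loewe_ikr, loewe_ikur, moreno_ina):
        for problem in (staircase_hh, staircase_mm, loewe_ikr, loewe_ikur, moreno_ina):
            assert problem.cost(problem.true_parameters) < problem.cost_threshold


class TestCost:
    def test_cost_nonnegative(self, fixture_problem, rng):
        for _ in range(10):
            p = fixture_problem.true_parameters * np.exp(rng.uniform(-2, 2, 3))
            assert fixture_problem.cost(p) >= 0.0

    def test_penalty_path_skips_model_solve(self, fixture_problem):
        tracker = Tracker()
        fixture_problem.attach_tracker(
            tracker, modification=Modification(parameter_bounds=True))
        try:
            outside = fixture_problem.bounds.upper * 2.0
            c = fixture_problem.cost(outside)
        finally:
            fixture_problem.detach_tracker()
        assert c >= 1e5
        assert tracker.cost_solves == 0
        assert tracker.out_of_bounds == 1

    def test_non_finite_parameters_rejected(self, fixture_problem):
        with pytest.raises(ValueError):
            fixture_problem.cost(np.array([np.nan, 0.05, 0.5]))

    def test_cost_invariant_to_modification_settings(self, fixture_problem):
        p = fixture_problem.true_parameters * 1.2
        base = fixture_problem.cost(p)
        for mod in (Modification(log_transform=True),
                    Modification(scale_transform=True, log_transform=True)):
            x = to_search_space(p, mod, fixture_problem)
            back = from_search_space(x, mod, fixture_problem)
            assert fixture_problem.cost(back) == pytest.approx(base, rel=1e-12)

    def test_residual_norm_equals_cost(self, fixture_problem):
        p = fixture_problem.true_parameters * 0.8
        r = fixture_problem.residuals(p)
        assert np.linalg.norm(r) == pytest.approx(fixture_problem.cost(p), rel=1e-12)


class TestGradient:
    def test_gradient_near_zero_at_noise_free_minimum(self, fixture_problem):
        g = fixture_problem.gradient(fixture_problem.true_parameters)
        assert np.linalg.norm(g) < 1e-6

    def test_gradient_matches_finite_differences(self, fixture_problem):
        p = fixture_problem.true_parameters * np.array([1.3, 0.9, 1.2])
        g = fixture_problem.gradient(p)
        fd = np.empty_like(p)
        for j in range(p.size):
            h = 1e-6 * abs(p[j])
            pp = p.copy(); pp[j] += h
            pm = p.copy(); pm[j] -= h
            fd[j] = (fixture_problem.cost(pp) - fixture_problem.cost(pm)) / (2 * h)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-3

    def test_conductance_direction_sign_matches_residual_correlation(self, fixture_problem):
        # overestimated conductance -> positive gradient component on g
        p = fixture_problem.true_parameters.copy()
        p[2] *= 1.5
        assert fixture_problem.gradient(p)[2] > 0
        p[2] = fixture_problem.true_parameters[2] * 0.5
        assert fixture_problem.gradient(p)[2] < 0

    def test_gradient_recorded_as_gradient_solve(self, fixture_problem):
        tracker = Tracker()
        fixture_problem.attach_tracker(tracker)
        try:
            fixture_problem.gradient(fixture_problem.true_parameters * 1.1)
        finally:
            fixture_problem.detach_tracker()
        assert tracker.grad_solves == 1 and tracker.cost_solves == 0


class TestSampling:
    def test_moreno_samples_within_quarter_band(self, moreno_ina):
        s = moreno_ina.sample_initial_parameters(10_000, seed=5)
        p = moreno_ina.true_parameters
        assert np.all(s > 0.75 * p - 1e-12) and np.all(s < 1.25 * p + 1e-12)

    def test_loewe_samples_respect_box(self, loewe_ikur):
        s = loewe_ikur.sample_initial_parameters(10_000, seed=6)
        assert np.all(s >= loewe_ikur.bounds.lower - 1e-12)
        assert np.all(s <= loewe_ikur.bounds.upper + 1e-12)

    def test_staircase_samples_satisfy_rate_bounds(self, staircase_hh):
        s = staircase_hh.sample_initial_parameters(300, seed=7)
        assert all(staircase_hh.rates_in_bounds(v) for v in s)
        assert np.all(s >= staircase_hh.bounds.lower)
        assert np.all(s <= staircase_hh.bounds.upper)

    def test_same_seed_gives_identical_starts(self, fixture_problem):
        a = fixture_problem.sample_initial_parameters(20, seed=11)
        b = fixture_problem.sample_initial_parameters(20, seed=11)
        assert np.array_equal(a, b)

    def test_n_below_one_rejected(self, fixture_problem):
        with pytest.raises(ValueError):
            fixture_problem.sample_initial_parameters(0, seed=1)


class TestSummaryStatistics:
    def test_cost_zero_at_truth(self, moreno_ina):
        assert moreno_ina.cost(moreno_ina.true_parameters) < 1e-12

    def test_activation_monotone_nondecreasing(self, moreno_ina):
        stats = compute_summary_statistics(moreno_ina.model,
                                           moreno_ina.true_parameters)
        assert np.all(np.diff(stats.activation[1]) >= -1e-9)

    def test_curve_ranges(self, moreno_ina):
        stats = compute_summary_statistics(moreno_ina.model,
                                           moreno_ina.true_parameters)
        for curve in (stats.activation[1], stats.inactivation[1], stats.recovery[1]):
            assert curve.min() >= 0.0 and curve.max() <= 1.0 + 1e-12
        assert np.all(stats.decay_time[1] > 0)

    def test_recovery_complete_at_long_interval(self, moreno_ina):
        stats = compute_summary_statistics(moreno_ina.model,
                                           moreno_ina.true_parameters)
        assert stats.recovery[1][-1] == pytest.approx(1.0, abs=0.02)
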