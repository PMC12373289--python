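"""ERT algebra, time-ratio arithmetic, bootstrap behaviour and the
all-pairs significance comparison."""

import numpy as np
import pytest
from scipy import stats

from chanbench.analysis import (
    bootstrap_ert,
    compare_approaches,
    expected_run_time,
    head_to_head,
    time_ratio,
)
from chanbench.tracking import RunResult


def _run(success, fe):
    return RunResult(success=success, status="s" if success else "f",
                     cost_solves=int(fe), grad_solves=0, out_of_bounds=0,
                     best_cost=0.0, best_params=None)


class TestExpectedRunTime:
    def test_all_successes_gives_ts(self):
        est = expected_run_time([_run(True, 500)] * 4)
        assert est.ert == est.T_s == 500.0
        assert est.p_hat == 1.0

    def test_direct_formula_evaluation(self):
        # T_s = 100, T_f = 200, p = 1/4: ERT = 100 + 200*3 = 700
        runs = [_run(True, 100)] + [_run(False, 200)] * 3
        est = expected_run_time(runs)
        assert est.ert == pytest.approx(700.0)

    def test_no_successes_is_infinite(self):
        est = expected_run_time([_run(False, 50)] * 3)
        assert np.isinf(est.ert)

    def test_ert_decreasing_in_success_rate(self):
        erts = []
        for x in (1, 2, 3, 4):
            runs = [_run(True, 100)] * x + [_run(False, 100)] * (5 - x)
            erts.append(expected_run_time(runs).ert)
        assert all(b < a for a, b in zip(erts, erts[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expected_run_time([])


class TestTimeRatio:
    @pytest.mark.parametrize("cost_t,grad_t,n,expected", [
        (0.00613, 0.0537, 9, 8.77),    # sensitivities win
        (0.00810, 0.108, 15, 13.3),
        (0.00575, 0.0604, 12, 10.5),
        (0.00619, 0.372, 25, 26.0),    # finite differences win
        (0.0575, 2.53, 16, 17.0),
    ])
    def test_benchmark_rows(self, cost_t, grad_t, n, expected):
        # printed values carry three significant figures
        assert time_ratio(cost_t, grad_t, n) == pytest.approx(expected, rel=5e-3)

    def test_spsa_override(self):
        assert time_ratio(1.0, 50.0, 9, is_spsa=True) == 2.0

    def test_fd_column_is_nplus1_cost_solves(self):
        # the hypothetical finite-difference gradient costs (n+1) solves
        assert (9 + 1) * 0.00613 == pytest.approx(0.0613, rel=1e-3)
        assert (15 + 1) * 0.00810 == pytest.approx(0.130, rel=5e-3)
        assert (16 + 1) * 0.0575 == pytest.approx(0.977, rel=1e-3)


class TestBootstrap:
    def test_all_failure_samples_finite(self):
        b = bootstrap_ert([_run(False, 40)] * 6, n_boot=3000, seed=0)
        assert np.all(np.isfinite(b)) and np.all(b > 0)

    def test_deterministic_under_seed(self):
        runs = [_run(True, 10), _run(False, 30), _run(True, 20)]
        assert np.array_equal(bootstrap_ert(runs, 500, seed=5),
                              bootstrap_ert(runs, 500, seed=5))

    def test_success_rate_posterior_matches_jeffreys_beta(self):
        """The bootstrapped rate given x successes of n is Beta(x+.5, n-x+.5).

        With every observed run a success, resampling cannot change the
        count, so the implied rate (1/ERT for unit times) must follow
        Beta(n+0.5, 0.5) exactly; checked by moments and a KS test.
        """
        n = 10
        runs = [_run(True, 1)] * n
        b = bootstrap_ert(runs, n_boot=10_000, seed=7)
        # all times = 1, so ERT = 1 + (1-p)/p = 1/p and p = 1/ERT
        p_samples = 1.0 / b
        ref = stats.beta(n + 0.5, 0.5)
        ks = stats.kstest(p_samples, ref.cdf)
        assert ks.pvalue > 0.01
        assert p_samples.mean() == pytest.approx(ref.mean(), abs=0.01)
        assert p_samples.std() == pytest.approx(ref.std(), rel=0.1)


class TestCompare:
    def test_identical_samples_are_tied(self):
        a = np.arange(100.0)
        out = compare_approaches(a, a)
        assert out["fraction_a_better"] == pytest.approx(0.5)
        assert not out["a_significant"] and not out["b_significant"]

    def test_strict_domination(self):
        a = np.arange(10.0)
        b = a + 100.0
        out = compare_approaches(a, b)
        assert out["fraction_a_better"] == 1.0
        assert out["a_significant"]

    def test_matches_brute_force_all_pairs(self, rng):
        a = rng.normal(0, 1, 100)
        b = rng.normal(0.3, 1, 100)
        a[:5] = b[:5]  # inject exact ties
        out = compare_approaches(a, b)
        wins = sum((ai < bj) + 0.5 * (ai == bj) for ai in a for bj in b)
        assert out["fraction_a_better"] == pytest.approx(wins / (100 * 100))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_approaches(np.array([]), np.array([1.0]))


class TestHeadToHead:
    def test_same_approach_is_undecided(self, fixture_problem):
        from chanbench.optimisers import PLAIN_TRR

        out = head_to_head(PLAIN_TRR, PLAIN_TRR, fixture_problem,
                           batch_size=4, seed=1, max_batches=2, n_boot=1000)
        assert out["winner"] is None

    def test_crippled_opponent_loses_quickly(self, fixture_problem):
        from chanbench.modifications import Modification
        from chanbench.optimisers import ApproachSpec, NEW_APPROACH

        # unbounded particle swarm wanders and stagnates on this problem
        crippled = ApproachSpec(name="crippled", citation="x", optimiser="pso",
                                category="PSO", uses_gradient=False,
                                modification=Modification())
        term = fixture_problem.default_termination(
            stagnation_window=150, max_model_solves=400, max_iterations=400)
        out = head_to_head(NEW_APPROACH, crippled, fixture_problem,
                           batch_size=5, seed=2, max_batches=4, n_boot=1000,
                           termination=term)
        assert out["winner"] == "A"
        assert out["n_batches"] <= 4

    def test_batches_share_start_vectors(self, fixture_problem, monkeypatch):
        from chanbench.optimisers import PLAIN_TRR
        import chanbench.optimisers as opt_mod

        seen = []
        original = opt_mod.run_approach

        def spy(spec, problem, x0, **kw):
            seen.append((spec.name, tuple(x0)))
            return original(spec, problem, x0, **kw)

        monkeypatch.setattr("chanbench.optimisers.run_approach", spy)
        head_to_head(PLAIN_TRR, PLAIN_TRR, fixture_problem,
                     batch_size=3, seed=3, max_batches=1, n_boot=500)
        starts_a = [x for name, x in seen[0::2]]
        starts_b = [x for name, x in seen[1::2]]
        assert starts_a == starts_b
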