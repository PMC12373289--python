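"""Performance statistics: Expected Run Time and bootstrap significance.

The Expected Run Time (ERT) of an approach under restarts is

    ERT = T_s + T_f * (1 - p_hat) / p_hat

where T_s and T_f are the mean times (in function evaluations, FEs) of the
successful and failed runs and p_hat the observed success fraction.
Gradient solves are first converted into FEs through a per-problem time
ratio: the cost of one gradient solve relative to one plain solve, taking
sensitivities or hypothetical finite differences ((n_parameters + 1) plain
solves), whichever is cheaper.

Uncertainty is quantified by a bootstrap in which the success probability
is drawn from the Jeffreys-prior posterior Beta(x + 0.5, nRun - x + 0.5):
the sampled rate is never exactly zero (the next restart may always
succeed), so every bootstrapped ERT is finite even for approaches that
failed on every observed run.  Two approaches differ 'significantly' when
one is better in at least 95% of all pairwise sample comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ERTEstimate",
    "expected_run_time",
    "time_ratio",
    "bootstrap_ert",
    "compare_approaches",
    "head_to_head",
]


@dataclass
class ERTEstimate:
    T_s: float       # mean successful-run time (FEs); NaN if no successes
    T_f: float       # mean failed-run time (FEs); NaN if no failures
    p_hat: float     # success fraction
    ert: float       # expected run time (FEs); inf when p_hat == 0
    n_run: int
    n_success: int


def expected_run_time(results) -> ERTEstimate:
    """Point estimate of the ERT from a list of run results.

    Accepts any objects with ``success`` and ``fe_time`` attributes.
    """
    results = list(results)
    if not results:
        raise ValueError("at least one run result is required")
    times = np.array([r.fe_time for r in results], dtype=float)
    succ = np.array([r.success for r in results], dtype=bool)
    n = times.size
    x = int(succ.sum())
    T_s = float(times[succ].mean()) if x else np.nan
    T_f = float(times[~succ].mean()) if x < n else np.nan
    p = x / n
    if x == 0:
        ert = np.inf
    elif x == n:
        ert = T_s
    else:
        ert = T_s + T_f * (1 - p) / p
    return ERTEstimate(T_s, T_f, p, float(ert), n, x)


def time_ratio(cost_time, grad_time, n_parameters, is_spsa=False) -> float:
    """FE-equivalent cost of one gradient solve.

    min(sensitivity time, (n_parameters + 1) * cost time) / cost time.
    Simultaneous-perturbation (SPSA) gradients need only two plain solves,
    so the ratio is fixed at 2 for that approach.
    """
    if is_spsa:
        return 2.0
    if cost_time <= 0 or grad_time <= 0:
        raise ValueError("solve times must be positive")
    fd_time = (n_parameters + 1) * cost_time
    return min(grad_time, fd_time) / cost_time


def bootstrap_ert(results, n_boot: int = 10_000, seed=None) -> np.ndarray:
    """Bootstrap distribution of the ERT; all samples finite and positive.

    Each replicate resamples the nRun runs with replacement; when a
    resample contains only successes the failure time is taken as a single
    random draw from the pooled observed times (and symmetrically for the
    success time), reflecting the extra uncertainty; the success rate is
    drawn from Beta(x + 0.5, nRun - x + 0.5).
    """
    results = list(results)
    n = len(results)
    if n < 1:
        raise ValueError("at least one run result is required")
    rng = np.random.default_rng(seed)
    times = np.array([r.fe_time for r in results], dtype=float)
    succ = np.array([r.success for r in results], dtype=bool)

    idx = rng.integers(0, n, size=(n_boot, n))
    s = succ[idx]                       # (n_boot, n)
    t = times[idx]
    x = s.sum(axis=1)

    with np.errstate(invalid="ignore"):
        T_s = np.where(x > 0, (t * s).sum(axis=1) / np.maximum(x, 1), np.nan)
        T_f = np.where(x < n, (t * ~s).sum(axis=1) / np.maximum(n - x, 1), np.nan)
    pooled = times[rng.integers(0, n, size=n_boot)]
    T_s = np.where(x == 0, pooled, T_s)
    pooled_f = times[rng.integers(0, n, size=n_boot)]
    T_f = np.where(x == n, pooled_f, T_f)

    p = rng.beta(x + 0.5, n - x + 0.5)
    return T_s + T_f * (1 - p) / p


def compare_approaches(samples_a, samples_b, level: float = 0.95) -> dict:
    """All-pairs comparison of two bootstrapped ERT sample sets.

    Lower ERT is better.  The fraction of pairs in which A beats B is
    computed exactly by sorting and rank counting (ties count half), which
    is equivalent to the nested double loop without materialising the
    pairs.  ``a_significant`` flags A better in at least ``level`` of the
    comparisons (and symmetrically for B).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample vectors")
    b_sorted = np.sort(b)
    less = np.searchsorted(b_sorted, a, side="left")      # b < a count... see below
    less_equal = np.searchsorted(b_sorted, a, side="right")
    # number of b strictly greater than a_i:
    greater = b.size - less_equal
    ties = less_equal - less
    wins = greater.sum() + 0.5 * ties.sum()
    frac = wins / (a.size * b.size)
    return {
        "fraction_a_better": float(frac),
        "a_significant": bool(frac >= level),
        "b_significant": bool(frac <= 1.0 - level),
        "n_comparisons": int(a.size) * int(b.size),
    }


def head_to_head(spec_a, spec_b, problem, batch_size=10, seed=0,
                 max_batches=10, n_boot=2000, termination=None) -> dict:
    """Run two approaches head-to-head until one is significantly better.

    Each batch samples fresh starting vectors and runs *both* approaches
    from the same starts; after every batch the accumulated runs are
    bootstrapped and compared.  Stops at significance or after
    ``max_batches`` batches (winner None).
    """
    from chanbench.optimisers import run_approach

    results_a, results_b = [], []
    rng = np.random.default_rng(seed)
    outcome = None
    batches_used = 0
    for batch in range(max_batches):
        batches_used = batch + 1
        starts = problem.sample_initial_parameters(
            batch_size, seed=int(rng.integers(0, 2**31 - 1)))
        for x0 in starts:
            sa = int(rng.integers(0, 2**31 - 1))
            sb = int(rng.integers(0, 2**31 - 1))
            results_a.append(run_approach(spec_a, problem, x0, seed=sa,
                                          termination=termination).run_result)
            results_b.append(run_approach(spec_b, problem, x0, seed=sb,
                                          termination=termination).run_result)
        boot_a = bootstrap_ert(results_a, n_boot, seed=int(rng.integers(0, 2**31 - 1)))
        boot_b = bootstrap_ert(results_b, n_boot, seed=int(rng.integers(0, 2**31 - 1)))
        cmp = compare_approaches(boot_a, boot_b)
        if cmp["a_significant"]:
            outcome = "A"
            break
        if cmp["b_significant"]:
            outcome = "B"
            break
    return {
        "winner": outcome,
        "n_runs": len(results_a),
        "n_batches": batches_used,
        "fraction_a_better": cmp["fraction_a_better"],
        "results_a": results_a,
        "results_b": results_b,
    }
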