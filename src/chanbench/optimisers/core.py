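"""Optimiser runners and the approach harness.

Optimisers see the problem only through a :class:`SearchView`: cost,
gradient, residuals and Jacobian in the (possibly transformed) search
space, plus the transformed parameter box when the approach uses bounds.
Every evaluation flows through the problem's tracker, which enforces the
shared termination criteria by raising
:class:`~chanbench.tracking.Terminated`; the harness catches it and
summarises the run.  All stochastic optimisers draw exclusively from the
numpy Generator they are handed, so runs are reproducible under a seed.

Implemented optimisers: trust-region-reflective least squares (TRR),
Levenberg-Marquardt, Nelder-Mead, Powell, conjugate gradients, SQP (all
via scipy.optimize), and in-package CMA-ES, particle swarm, a real-coded
genetic algorithm and Hooke-Jeeves pattern search, plus the sequential
(``a+b``) and interleaved (``a/b``) hybrid combinators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from chanbench.modifications import (
    Modification,
    from_search_space,
    search_gradient_factor,
    search_space_bounds,
    to_search_space,
)
from chanbench.tracking import RunResult, Terminated, Tracker, TerminationSpec
from chanbench.optimisers.registry import ApproachSpec, IMPLEMENTED_OPTIMISERS

__all__ = ["OptimiserResult", "SearchView", "run_approach"]

_BIG = 1e12


@dataclass
class OptimiserResult:
    best_params: np.ndarray | None  # model space
    best_cost: float
    status: str
    run_result: RunResult


class SearchView:
    """Problem surface exposed to an optimiser, in search-space coordinates."""

    def __init__(self, problem, modification: Modification):
        self.problem = problem
        self.modification = modification

    def to_search(self, params):
        return to_search_space(params, self.modification, self.problem)

    def from_search(self, x):
        return from_search_space(x, self.modification, self.problem)

    def _params(self, x):
        p = self.from_search(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(p)):
            return None
        return p

    def cost(self, x) -> float:
        p = self._params(x)
        if p is None:
            return _BIG
        return self.problem.cost(p)

    def gradient(self, x) -> np.ndarray:
        p = self._params(x)
        if p is None:
            return np.zeros(np.asarray(x).size)
        g = self.problem.gradient(p)
        return g * search_gradient_factor(p, self.modification, self.problem)

    def residuals(self, x) -> np.ndarray:
        p = self._params(x)
        if p is None:
            return np.full(self.problem._data_size(), np.sqrt(_BIG))
        return self.problem.residuals(p)

    def jacobian(self, x) -> np.ndarray:
        p = self._params(x)
        if p is None:
            return np.zeros((self.problem._data_size(), np.asarray(x).size))
        J = self.problem.residual_jacobian(p)
        return J * search_gradient_factor(p, self.modification, self.problem)[None, :]

    @property
    def bounds(self):
        """Search-space box, or None when the approach does not use bounds."""
        if self.modification.parameter_bounds or self.problem.always_bounded:
            return search_space_bounds(self.modification, self.problem)
        return None

    def bounds_or_default(self, x0, width=2.0):
        """A working box for population optimisers when no bounds are set."""
        b = self.bounds
        if b is not None:
            return b
        span = width * np.maximum(np.abs(x0), 1.0)
        return x0 - span, x0 + span


def _interior(x0, bounds, margin=1e-10):
    if bounds is None:
        return np.asarray(x0, dtype=float)
    lo, hi = bounds
    eps = margin + 1e-12 * (hi - lo)
    return np.clip(x0, lo + eps, hi - eps)


# ---------------------------------------------------------------------------
# scipy-backed optimisers
# ---------------------------------------------------------------------------

def _opt_trr(view, x0, rng, max_iter, hyper):
    b = view.bounds
    bounds = (-np.inf, np.inf) if b is None else b
    optimize.least_squares(
        view.residuals, _interior(x0, b), jac=view.jacobian, bounds=bounds,
        method="trf", max_nfev=max_iter,
        xtol=hyper.get("xtol", 1e-10), ftol=hyper.get("ftol", 1e-10),
        gtol=hyper.get("gtol", 1e-10),
    )


def _opt_lm(view, x0, rng, max_iter, hyper):
    optimize.least_squares(view.residuals, np.asarray(x0, float),
                           jac=view.jacobian, method="lm", max_nfev=max_iter)


def _scipy_minimize(method, with_grad):
    def runner(view, x0, rng, max_iter, hyper):
        b = view.bounds
        bounds = None if b is None else list(zip(b[0], b[1]))
        kw = {}
        if with_grad:
            kw["jac"] = view.gradient
        if method in ("Nelder-Mead", "Powell"):
            kw["bounds"] = bounds
        elif method == "SLSQP":
            kw["bounds"] = bounds
        optimize.minimize(view.cost, _interior(x0, b), method=method,
                          options={"maxiter": max_iter}, **kw)
    return runner


_opt_nelder_mead = _scipy_minimize("Nelder-Mead", with_grad=False)
_opt_powell = _scipy_minimize("Powell", with_grad=False)
_opt_cg = _scipy_minimize("CG", with_grad=True)
_opt_sqp = _scipy_minimize("SLSQP", with_grad=True)


# ---------------------------------------------------------------------------
# In-package stochastic optimisers
# ---------------------------------------------------------------------------

def _opt_cma_es(view, x0, rng, max_iter, hyper):
    """(mu/mu_w, lambda)-CMA-ES with rank-one and rank-mu covariance updates."""
    n = np.asarray(x0).size
    lo, hi = view.bounds_or_default(x0)
    lam = int(hyper.get("popsize", 4 + int(3 * np.log(n))))
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / np.sum(w**2)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    ds = 1 + 2 * max(0.0, np.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    scale = (hi - lo) / 4.0
    m = (np.clip(x0, lo, hi) - lo) / np.maximum(hi - lo, 1e-300)  # unit cube
    sigma = float(hyper.get("sigma0", 0.3))
    C = np.eye(n)
    ps = np.zeros(n)
    pc = np.zeros(n)
    evals = 0
    while evals < max_iter:
        D2, B = np.linalg.eigh(C)
        D = np.sqrt(np.maximum(D2, 1e-20))
        z = rng.standard_normal((lam, n))
        y = z @ np.diag(D) @ B.T
        xs = m + sigma * y
        costs = np.empty(lam)
        for i in range(lam):
            xi = lo + np.clip(xs[i], 0.0, 1.0) * (hi - lo)
            costs[i] = view.cost(xi)
            evals += 1
        order = np.argsort(costs)
        y_w = w @ y[order[:mu]]
        m = m + sigma * y_w
        # step-size control
        C_inv_sqrt = B @ np.diag(1.0 / D) @ B.T
        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mu_eff) * (C_inv_sqrt @ y_w)
        sigma *= np.exp((cs / ds) * (np.linalg.norm(ps) / chi_n - 1))
        hsig = float(np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * evals / lam))
                     < (1.4 + 2 / (n + 1)) * chi_n)
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mu_eff) * y_w
        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(w, y[order[:mu]]))
        C = ((1 - c1 - cmu) * C
             + c1 * (np.outer(pc, pc) + (1 - hsig) * cc * (2 - cc) * C)
             + cmu * rank_mu)
        C = (C + C.T) / 2
        if sigma < 1e-12:
            break


def _opt_pso(view, x0, rng, max_iter, hyper):
    """Global-best particle swarm with constriction-style coefficients."""
    n = np.asarray(x0).size
    lo, hi = view.bounds_or_default(x0)
    n_part = int(hyper.get("n_particles", 20))
    w = hyper.get("inertia", 0.729)
    c1 = hyper.get("c_personal", 1.49445)
    c2 = hyper.get("c_global", 1.49445)
    pos = rng.uniform(lo, hi, size=(n_part, n))
    pos[0] = np.clip(x0, lo, hi)
    vel = np.zeros_like(pos)
    vmax = 0.2 * (hi - lo)
    pbest = pos.copy()
    pbest_cost = np.array([view.cost(p) for p in pos])
    g = int(np.argmin(pbest_cost))
    evals = n_part
    while evals < max_iter:
        r1 = rng.uniform(size=(n_part, n))
        r2 = rng.uniform(size=(n_part, n))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (pbest[g] - pos)
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(n_part):
            c = view.cost(pos[i])
            evals += 1
            if c < pbest_cost[i]:
                pbest_cost[i] = c
                pbest[i] = pos[i]
        g = int(np.argmin(pbest_cost))


def _opt_ga(view, x0, rng, max_iter, hyper):
    """Real-coded genetic algorithm: tournament selection, blend crossover,
    Gaussian mutation, one-elite replacement."""
    n = np.asarray(x0).size
    lo, hi = view.bounds_or_default(x0)
    pop_size = int(hyper.get("pop_size", 50))
    p_mut = hyper.get("p_mutation", 0.1)
    alpha = hyper.get("blend_alpha", 0.5)
    pop = rng.uniform(lo, hi, size=(pop_size, n))
    pop[0] = np.clip(x0, lo, hi)
    costs = np.array([view.cost(p) for p in pop])
    evals = pop_size
    while evals < max_iter:
        new = np.empty_like(pop)
        elite = int(np.argmin(costs))
        new[0] = pop[elite]
        for i in range(1, pop_size):
            a, b = rng.integers(0, pop_size, 2)
            pa = pop[a] if costs[a] <= costs[b] else pop[b]
            a, b = rng.integers(0, pop_size, 2)
            pb = pop[a] if costs[a] <= costs[b] else pop[b]
            span = np.abs(pa - pb)
            child = rng.uniform(np.minimum(pa, pb) - alpha * span,
                                np.maximum(pa, pb) + alpha * span)
            mask = rng.uniform(size=n) < p_mut
            child[mask] += rng.normal(0, 0.1 * (hi - lo)[mask])
            new[i] = np.clip(child, lo, hi)
        pop = new
        costs = np.array([view.cost(p) for p in pop])
        evals += pop_size


def _opt_pattern_search(view, x0, rng, max_iter, hyper):
    """Hooke-Jeeves pattern search with step halving."""
    b = view.bounds
    x = _interior(np.asarray(x0, dtype=float), b)
    n = x.size
    if b is not None:
        step = 0.1 * (b[1] - b[0])
    else:
        step = 0.1 * np.maximum(np.abs(x), 1.0)
    fx = view.cost(x)
    evals = 1
    min_step = 1e-10
    while evals < max_iter and np.max(step) > min_step:
        improved = False
        base = x.copy()
        for i in range(n):
            for s in (+1.0, -1.0):
                trial = x.copy()
                trial[i] += s * step[i]
                if b is not None:
                    trial = np.clip(trial, b[0], b[1])
                c = view.cost(trial)
                evals += 1
                if c < fx:
                    fx, x = c, trial
                    improved = True
                    break
        if improved:
            # pattern move: keep going in the successful direction
            trial = x + (x - base)
            if b is not None:
                trial = np.clip(trial, b[0], b[1])
            c = view.cost(trial)
            evals += 1
            if c < fx:
                fx, x = c, trial
        else:
            step = step / 2.0


_BASE_OPTIMISERS = {
    "trr": _opt_trr,
    "lm": _opt_lm,
    "nelder_mead": _opt_nelder_mead,
    "powell": _opt_powell,
    "conjugate_gd": _opt_cg,
    "sqp": _opt_sqp,
    "cma_es": _opt_cma_es,
    "pso": _opt_pso,
    "ga": _opt_ga,
    "pattern_search": _opt_pattern_search,
}


def _best_start(view, fallback):
    best = view.problem.tracker.best_params if view.problem.tracker else None
    if best is None:
        return np.asarray(fallback, dtype=float)
    try:
        return view.to_search(best)
    except ValueError:
        return np.asarray(fallback, dtype=float)


def _sequential(first, second, split=0.5):
    def runner(view, x0, rng, max_iter, hyper):
        budget1 = max(int(split * max_iter), 1)
        _BASE_OPTIMISERS[first](view, x0, rng, budget1, hyper)
        x1 = _best_start(view, x0)
        _BASE_OPTIMISERS[second](view, x1, rng, max_iter - budget1, hyper)
    return runner


def _interleaved(first, second, tail=None, chunk=250, local=80):
    def runner(view, x0, rng, max_iter, hyper):
        used = 0
        x = np.asarray(x0, dtype=float)
        while used < max_iter:
            _BASE_OPTIMISERS[first](view, x, rng, min(chunk, max_iter - used), hyper)
            used += chunk
            if used >= max_iter:
                break
            x = _best_start(view, x0)
            _BASE_OPTIMISERS[second](view, x, rng, min(local, max_iter - used), hyper)
            used += local
            x = _best_start(view, x0)
        if tail is not None:
            _BASE_OPTIMISERS[tail](view, _best_start(view, x0), rng, max_iter, hyper)
    return runner


_OPTIMISERS = dict(_BASE_OPTIMISERS)
_OPTIMISERS["pso+trr"] = _sequential("pso", "trr")
_OPTIMISERS["pso+nm"] = _sequential("pso", "nelder_mead")
_OPTIMISERS["pso/trr"] = _interleaved("pso", "trr")
_OPTIMISERS["pso/nm"] = _interleaved("pso", "nelder_mead")
_OPTIMISERS["pso/trr+trr"] = _interleaved("pso", "trr", tail="trr")


# ---------------------------------------------------------------------------
# Harness
# ---------------------------------------------------------------------------

def run_approach(spec: ApproachSpec, problem, initial_params, seed=None,
                 termination: TerminationSpec | None = None) -> OptimiserResult:
    """Run one optimisation of ``problem`` from ``initial_params``.

    The optimiser touches the problem only through the modification layer;
    the tracker records every evaluation and enforces the shared
    termination criteria.  Fully deterministic for a given seed and start.
    """
    if spec.optimiser not in IMPLEMENTED_OPTIMISERS:
        raise NotImplementedError(
            f"optimiser {spec.optimiser!r} (approach {spec.name}) is registered "
            "but has no runner in this package; implemented optimisers: "
            f"{sorted(IMPLEMENTED_OPTIMISERS)}")
    initial_params = np.asarray(initial_params, dtype=float)
    if initial_params.size != problem.n_parameters:
        raise ValueError("initial parameter vector has the wrong dimension")

    max_iter = 10_000 if spec.category == "GA" else 25_000
    if termination is None:
        termination = problem.default_termination(max_iterations=max_iter,
                                                  max_model_solves=max_iter)

    tracker = Tracker(keep_records=False)
    problem.attach_tracker(tracker, termination, spec.modification)
    view = SearchView(problem, spec.modification)
    rng = np.random.default_rng(seed)
    status = None
    try:
        x0 = view.to_search(initial_params)
        _OPTIMISERS[spec.optimiser](view, x0, rng, termination.max_iterations,
                                    spec.modification.hyperparameters)
    except Terminated as t:
        status = t.status
    finally:
        problem.detach_tracker()

    ratio = 2.0 if spec.optimiser == "spsa" else problem.time_ratio
    run_result = tracker.summarise(termination, time_ratio=ratio, status=status)
    return OptimiserResult(
        best_params=tracker.best_params,
        best_cost=tracker.best_cost,
        status=run_result.status,
        run_result=run_result,
    )
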