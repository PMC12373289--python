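"""Benchmark problems: black boxes exposing cost, gradient and sampling.

Each problem bundles a channel model, voltage protocol(s), synthetic data
generated at known true parameters, a cost function, a seeded
initial-parameter sampling region (which doubles as the parameter bounds),
rate bounds, a log-transform index set and a success cost threshold.

Five benchmark problems are provided plus a fast three-parameter fixture:

=============  ======================  ==========  ======  =====
name           model                   cost        params  noise
=============  ======================  ==========  ======  =====
staircase_hh   IKr Hodgkin-Huxley      trace RMSE       9  yes
staircase_mm   IKr Markov (5 states)   trace RMSE      15  yes
loewe_ikr      IKr Hodgkin-Huxley      trace RMSE      12  no
loewe_ikur     IKur Hodgkin-Huxley     trace RMSE      25  no
moreno_ina     INa Markov (5 states)   summary          16  no
fixture_hh     1-gate toy              trace RMSE       3  no
=============  ======================  ==========  ======  =====

The Staircase problems always enforce parameter and rate bounds, whatever
the approach's modification, because their sampling region is broad enough
that exterior points routinely break the solver.  Noise-free problems have
cost exactly zero at the true parameters (the data are regenerated from the
same code path).  From the optimiser's point of view the problem never
changes between approaches: sampling, data and cost are independent of any
transform settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chanbench import catalogue
from chanbench.models import HHModel, MarkovModel
from chanbench.modifications import (
    BoundsSpec,
    Modification,
    check_bounds,
    max_rate,
    penalty,
    penalty_gradient,
)
from chanbench.solvers import (
    SimResult,
    SolverSettings,
    solve,
    solve_with_sensitivities,
)
from chanbench.tracking import EvaluationRecord, Terminated, Tracker, TerminationSpec

__all__ = [
    "SamplingSpec",
    "SummaryStatistics",
    "BenchmarkProblem",
    "build_problem",
    "generate_data",
    "compute_summary_statistics",
    "PROBLEM_NAMES",
]

# Cost assigned to a failed simulation: worse than any in-bounds cost and
# any penalty, and rankable by how much of the trace failed.
_FAILURE_BASE = 1e5

PROBLEM_NAMES = (
    "staircase_hh",
    "staircase_mm",
    "loewe_ikr",
    "loewe_ikur",
    "moreno_ina",
    "fixture_hh",
)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

@dataclass
class SamplingSpec:
    """Per-parameter initial-guess sampling region.

    ``kinds`` holds one tuple per parameter:

    * ``('log_factor', lo, hi)``  -- log-uniform in [lo*p_true, hi*p_true]
    * ``('offset', w)``           -- uniform in p_true +/- w
    * ``('fraction', f)``         -- uniform in p_true * (1 +/- f)
    * ``('log_box', lo, hi)``     -- log-uniform in the absolute box [lo, hi]
    * ``('box', lo, hi)``         -- uniform in the absolute box [lo, hi]

    ``reject_rate_bounds`` turns on rejection sampling against the rate
    bounds (the Staircase sampling region): vectors are drawn from the
    rectangular parameter box and kept only if every transition rate's
    maximum over the voltage range lies strictly inside its bounds.
    """

    kinds: list
    reject_rate_bounds: bool = False
    max_attempts: int = 1_000_000

    def box(self, true_params):
        """The rectangular bounds implied by the sampling region."""
        lo = np.empty(len(self.kinds))
        hi = np.empty(len(self.kinds))
        for i, (kind, *args) in enumerate(self.kinds):
            p = true_params[i]
            if kind == "log_factor":
                lo[i], hi[i] = args[0] * p, args[1] * p
            elif kind == "offset":
                lo[i], hi[i] = p - args[0], p + args[0]
            elif kind == "fraction":
                lo[i], hi[i] = p * (1 - args[0]), p * (1 + args[0])
            elif kind in ("log_box", "box"):
                lo[i], hi[i] = args
            else:
                raise ValueError(f"unknown sampling kind {kind!r}")
        return lo, hi

    def _draw(self, n, rng, true_params):
        out = np.empty((n, len(self.kinds)))
        for i, (kind, *args) in enumerate(self.kinds):
            p = true_params[i]
            if kind == "log_factor":
                out[:, i] = np.exp(rng.uniform(np.log(args[0] * p), np.log(args[1] * p), n))
            elif kind == "offset":
                out[:, i] = rng.uniform(p - args[0], p + args[0], n)
            elif kind == "fraction":
                out[:, i] = rng.uniform(p * (1 - args[0]), p * (1 + args[0]), n)
            elif kind == "log_box":
                out[:, i] = np.exp(rng.uniform(np.log(args[0]), np.log(args[1]), n))
            else:
                out[:, i] = rng.uniform(args[0], args[1], n)
        return out

    def sample(self, n, rng, true_params, rate_ok=None):
        if not self.reject_rate_bounds or rate_ok is None:
            return self._draw(n, rng, true_params)
        kept, attempts = [], 0
        need = n
        while need > 0:
            batch = max(4 * need, 64)
            attempts += batch
            if attempts > self.max_attempts:
                raise RuntimeError("rejection sampling exceeded the attempt budget")
            cand = self._draw(batch, rng, true_params)
            mask = np.fromiter((rate_ok(c) for c in cand), dtype=bool, count=batch)
            for c in cand[mask]:
                kept.append(c)
                if len(kept) == n:
                    break
            need = n - len(kept)
        return np.array(kept)


@dataclass
class SummaryStatistics:
    """Four biomarker curves used by the Moreno-style INa problem.

    Steady-state curves and recovery fractions live in [0, 1]; the decay
    times are positive (ms).
    """

    inactivation: tuple  # (V prepulse, normalised peak)
    activation: tuple    # (V test, normalised conductance)
    recovery: tuple      # (interpulse interval ms, fractional recovery)
    decay_time: tuple    # (V test, time to 50% decay, ms)

    def concatenate(self):
        return np.concatenate([
            np.asarray(self.inactivation[1], dtype=float),
            np.asarray(self.activation[1], dtype=float),
            np.asarray(self.recovery[1], dtype=float),
            np.asarray(self.decay_time[1], dtype=float),
        ])


def compute_summary_statistics(model: MarkovModel, params,
                               spec=None) -> SummaryStatistics | None:
    """Run the two-pulse/step protocol families and extract the biomarkers.

    Returns None on simulation failure (the caller maps this to the failure
    cost).  See :mod:`chanbench.catalogue` for the protocol tables.
    """
    spec = spec or catalogue.moreno_summary_spec()
    E = model.E_rev

    def peak(protocol):
        res = solve(model, protocol, params, method="markov_analytic")
        if res.failed:
            return None
        return float(np.max(np.abs(res.current)))

    # steady-state activation: normalised peak conductance vs test voltage
    act_v, act_g = [], []
    for Vt, proto in spec["activation"]:
        p = peak(proto)
        if p is None:
            return None
        act_v.append(Vt)
        act_g.append(p / max(abs(Vt - E), 1e-9))
    act_g = np.array(act_g)
    act_g = act_g / max(act_g.max(), 1e-12)

    # steady-state inactivation: normalised peak during fixed test pulse
    ssi_v, ssi_p = [], []
    for Vpre, proto in spec["inactivation"]:
        p = peak(proto)
        if p is None:
            return None
        ssi_v.append(Vpre)
        ssi_p.append(p)
    ssi_p = np.array(ssi_p)
    ssi_p = ssi_p / max(ssi_p.max(), 1e-12)

    # recovery from inactivation: paired-pulse peak ratio vs interval
    rec_t, rec_f = [], []
    for dt, proto, w1, w2 in spec["recovery"]:
        res = solve(model, proto, params, method="markov_analytic")
        if res.failed:
            return None
        a = np.abs(res.current)
        p1 = float(a[w1].max())
        p2 = float(a[w2].max())
        rec_t.append(dt)
        rec_f.append(min(p2 / max(p1, 1e-12), 1.0))

    # time from peak to 50% decay of the current
    dec_v, dec_t = [], []
    for Vt, proto, window in spec["decay"]:
        res = solve(model, proto, params, method="markov_analytic")
        if res.failed:
            return None
        t = proto.sampling_times[window]
        a = np.abs(res.current[window])
        k = int(np.argmax(a))
        half = 0.5 * a[k]
        below = np.nonzero(a[k:] <= half)[0]
        if below.size == 0:
            t50 = t[-1] - t[k]  # never decayed within the window
        else:
            j = k + below[0]
            if j == k:
                t50 = 0.0
            else:
                # linear interpolation between the bracketing samples
                f = (a[j - 1] - half) / max(a[j - 1] - a[j], 1e-15)
                t50 = (t[j - 1] + f * (t[j] - t[j - 1])) - t[k]
        dec_v.append(Vt)
        dec_t.append(max(t50, 0.0))

    return SummaryStatistics(
        inactivation=(np.array(ssi_v), ssi_p),
        activation=(np.array(act_v), act_g),
        recovery=(np.array(rec_t), np.array(rec_f)),
        decay_time=(np.array(dec_v), np.array(dec_t)),
    )


# ---------------------------------------------------------------------------
# Problem
# ---------------------------------------------------------------------------

class BenchmarkProblem:
    """A black-box parameter-estimation problem.

    Optimisers interact with the problem only through :meth:`cost`,
    :meth:`gradient`, :meth:`residuals` / :meth:`residual_jacobian` and
    :meth:`sample_initial_parameters`.  When a tracker is attached every
    evaluation is recorded and termination criteria are checked; a firing
    criterion raises :class:`~chanbench.tracking.Terminated`, which the run
    harness catches.
    """

    def __init__(self, name, model, protocols, true_parameters, solver,
                 sampling: SamplingSpec, log_indices, cost_threshold,
                 n_run_default, time_ratio, data_seed=0, noise_sigma=None,
                 rate_upper_overrides=None, always_bounded=False,
                 solver_settings=None, summary_spec=None):
        self.name = name
        self.model = model
        self.protocols = list(protocols)
        self.true_parameters = np.asarray(true_parameters, dtype=float)
        self.solver = solver
        self.sampling = sampling
        self.log_indices = np.asarray(log_indices, dtype=int)
        self.cost_threshold = float(cost_threshold)
        self.n_run_default = int(n_run_default)
        self.time_ratio = float(time_ratio)
        self.data_seed = int(data_seed)
        self.noise_sigma = noise_sigma
        self.always_bounded = bool(always_bounded)
        self.solver_settings = solver_settings or SolverSettings()
        self.summary_spec = summary_spec

        self.rate_expressions = list(model.rates)
        lo, hi = sampling.box(self.true_parameters)
        rl = np.full(len(self.rate_expressions), catalogue.RATE_LOWER)
        ru = np.full(len(self.rate_expressions), catalogue.RATE_UPPER)
        if rate_upper_overrides:
            for j, v in rate_upper_overrides.items():
                ru[j] = v
        self.bounds = BoundsSpec(lo, hi, rl, ru)

        self.tracker: Tracker | None = None
        self.termination: TerminationSpec | None = None
        self.active_modification = Modification()

        self.data = None
        self._weights = None

    # -- configuration -----------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return self.model.n_parameters

    def attach_tracker(self, tracker: Tracker, termination: TerminationSpec | None = None,
                       modification: Modification | None = None):
        self.tracker = tracker
        self.termination = termination
        if modification is not None:
            self.active_modification = modification

    def detach_tracker(self):
        self.tracker = None
        self.termination = None
        self.active_modification = Modification()

    def default_termination(self, **overrides) -> TerminationSpec:
        kw = dict(cost_threshold=self.cost_threshold)
        kw.update(overrides)
        return TerminationSpec(**kw)

    def rates_in_bounds(self, params) -> bool:
        for j, rate in enumerate(self.rate_expressions):
            r = max_rate(rate, params)
            if not np.isfinite(r):
                return False
            if r <= self.bounds.rate_lower[j] or r >= self.bounds.rate_upper[j]:
                return False
        return True

    # -- data --------------------------------------------------------------
    def _simulate_vector(self, params, with_sens=False):
        """Model output as a flat vector (trace or summary curves).

        Returns (y, jac_or_None, n_failed) with y None on failure.
        """
        if self.summary_spec is not None:
            if with_sens:
                return self._summary_fd_jacobian(params)
            stats = compute_summary_statistics(self.model, params, self.summary_spec)
            if stats is None:
                return None, None, self._data_size()
            return stats.concatenate(), None, 0

        ys, jacs, computed = [], [], 0
        for proto in self.protocols:
            if with_sens:
                res = solve_with_sensitivities(self.model, proto, params,
                                               self.solver_settings)
            else:
                res = solve(self.model, proto, params, method=self.solver,
                            settings=self.solver_settings)
            if res.failed:
                return None, None, self._data_size() - computed
            ys.append(res.current)
            computed += res.current.size
            if with_sens:
                jacs.append(res.sensitivities)
        y = np.concatenate(ys)
        return y, (np.vstack(jacs) if with_sens else None), 0

    def _summary_fd_jacobian(self, params):
        y0, _, nf = self._simulate_vector(params, with_sens=False)
        if y0 is None:
            return None, None, nf
        params = np.asarray(params, dtype=float)
        h = 1e-6 * np.maximum(np.abs(params), 1e-6)
        J = np.empty((y0.size, params.size))
        for j in range(params.size):
            pp = params.copy(); pp[j] += h[j]
            pm = params.copy(); pm[j] -= h[j]
            yp, _, _ = self._simulate_vector(pp)
            ym, _, _ = self._simulate_vector(pm)
            if yp is None or ym is None:
                return None, None, self._data_size()
            J[:, j] = (yp - ym) / (2 * h[j])
        return y0, J, 0

    def _data_size(self) -> int:
        if self.data is not None:
            return self.data.size
        return sum(p.sampling_times.size for p in self.protocols)

    def set_data(self, seed=None):
        """(Re)generate the problem data deterministically from a seed."""
        seed = self.data_seed if seed is None else seed
        y, _, _ = self._simulate_vector(self.true_parameters)
        if y is None:
            raise RuntimeError(f"data generation failed for {self.name}")
        if self.noise_sigma is not None:
            rng = np.random.default_rng(seed)
            y = y + rng.normal(0.0, self.noise_sigma, y.size)
        self.data = y
        self._weights = np.ones_like(y)
        if self.summary_spec is not None:
            # the decay-time curve is in ms while the other biomarkers are
            # dimensionless; weight it to a comparable scale
            n_dec = len(self.summary_spec["decay"])
            w = np.ones_like(y)
            dec = y[-n_dec:]
            w[-n_dec:] = 1.0 / max(np.abs(dec).mean(), 1e-9)
            self._weights = w
        return self.data

    # -- evaluation --------------------------------------------------------
    def _record(self, params, in_bounds, solved, with_sens, cost):
        if self.tracker is None:
            return
        self.tracker.record(EvaluationRecord(
            params=np.array(params, dtype=float), in_bounds=in_bounds,
            solved=solved, with_sensitivities=with_sens, cost=cost))
        if self.termination is not None:
            status = self.tracker.check_termination(self.termination)
            if status != "running":
                raise Terminated(status)

    def _penalty_value(self, params):
        mod = self.active_modification
        check_p = mod.parameter_bounds or self.always_bounded
        check_r = mod.rate_bounds or self.always_bounded
        return penalty(params, self.bounds, self.rate_expressions,
                       check_params=check_p, check_rates=check_r)

    def _weighted_residuals(self, y):
        n = self.data.size
        return self._weights * (y - self.data) / np.sqrt(n)

    def cost(self, params) -> float:
        """RMSE against the data, or the penalty when bounds are violated.

        Penalised points never solve the model; failed solves map to a
        large finite cost so optimisers can still rank them.
        """
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        in_bounds, _ = check_bounds(params, self.active_modification, self)
        if not in_bounds:
            c = self._penalty_value(params)
            self._record(params, False, False, False, c)
            return c
        y, _, n_failed = self._simulate_vector(params)
        if y is None:
            c = _FAILURE_BASE + n_failed
        else:
            c = float(np.linalg.norm(self._weighted_residuals(y)))
        self._record(params, True, True, False, c)
        return c

    def residuals(self, params) -> np.ndarray:
        """Weighted residual vector r with ||r|| equal to the RMSE cost.

        Out-of-bounds and failed points return a constant vector whose
        squared norm equals the penalty/failure cost, keeping least-squares
        optimisers able to rank them.
        """
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        n = self._data_size()
        in_bounds, _ = check_bounds(params, self.active_modification, self)
        if not in_bounds:
            c = self._penalty_value(params)
            self._record(params, False, False, False, c)
            return np.full(n, np.sqrt(c / n))
        y, _, n_failed = self._simulate_vector(params)
        if y is None:
            c = _FAILURE_BASE + n_failed
            self._record(params, True, True, False, c)
            return np.full(n, np.sqrt(c / n))
        r = self._weighted_residuals(y)
        self._record(params, True, True, False, float(np.linalg.norm(r)))
        return r

    def gradient(self, params) -> np.ndarray:
        """Gradient of the cost via a sensitivity solve.

        For penalised points the subgradient of the penalty is returned.
        Recorded as a gradient evaluation.
        """
        params = np.asarray(params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite parameters")
        mod = self.active_modification
        in_bounds, _ = check_bounds(params, mod, self)
        if not in_bounds:
            g = penalty_gradient(params, self.bounds, self.rate_expressions,
                                 check_params=mod.parameter_bounds or self.always_bounded,
                                 check_rates=mod.rate_bounds or self.always_bounded)
            self._record(params, False, False, False, self._penalty_value(params))
            return g
        y, J, n_failed = self._simulate_vector(params, with_sens=True)
        if y is None:
            self._record(params, True, True, True, _FAILURE_BASE + n_failed)
            return np.zeros(params.size)
        r = self._weighted_residuals(y)
        c = float(np.linalg.norm(r))
        self._record(params, True, True, True, c)
        Jw = (self._weights[:, None] * J) / np.sqrt(self.data.size)
        return (Jw.T @ r) / max(c, 1e-14)

    def residual_jacobian(self, params) -> np.ndarray:
        """Jacobian of :meth:`residuals`; a sensitivity solve."""
        params = np.asarray(params, dtype=float)
        n = self._data_size()
        mod = self.active_modification
        in_bounds, _ = check_bounds(params, mod, self)
        if not in_bounds:
            c = self._penalty_value(params)
            g = penalty_gradient(params, self.bounds, self.rate_expressions,
                                 check_params=mod.parameter_bounds or self.always_bounded,
                                 check_rates=mod.rate_bounds or self.always_bounded)
            self._record(params, False, False, False, c)
            # d/dp sqrt(Pen/n) rows
            return np.tile(g / (2 * np.sqrt(max(c, 1e-14) * n)), (n, 1))
        y, J, n_failed = self._simulate_vector(params, with_sens=True)
        if y is None:
            self._record(params, True, True, True, _FAILURE_BASE + n_failed)
            return np.zeros((n, params.size))
        r = self._weighted_residuals(y)
        self._record(params, True, True, True, float(np.linalg.norm(r)))
        return (self._weights[:, None] * J) / np.sqrt(self.data.size)

    # -- sampling ----------------------------------------------------------
    def sample_initial_parameters(self, n, seed=None) -> np.ndarray:
        """n starting vectors from the problem's sampling region.

        Independent of any modification settings, so all approaches share
        the same starts for a given seed.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        rate_ok = self.rates_in_bounds if self.sampling.reject_rate_bounds else None
        return self.sampling.sample(n, rng, self.true_parameters, rate_ok)

    # -- io ----------------------------------------------------------------
    def data_to_csv(self, path):
        if self.summary_spec is not None:
            pd.DataFrame({"value": self.data}).to_csv(path, index=False)
            return
        times = np.concatenate([p.sampling_times for p in self.protocols])
        pd.DataFrame({"time_ms": times, "current": self.data}).to_csv(path, index=False)

    def __repr__(self):
        return (f"<BenchmarkProblem {self.name}: {self.n_parameters} parameters, "
                f"threshold {self.cost_threshold:g}>")


def generate_data(problem: BenchmarkProblem, seed=None) -> np.ndarray:
    """Regenerate a problem's data (noise-free problems ignore the noise
    stream; Staircase problems add iid Gaussian noise, deterministic in
    the seed)."""
    return problem.set_data(seed)


def build_problem(name: str, data_seed=None) -> BenchmarkProblem:
    """Construct a fully-initialised benchmark problem by name."""
    if name not in PROBLEM_NAMES:
        raise KeyError(f"unknown problem {name!r}; choose from {PROBLEM_NAMES}")
    problem = catalogue.BUILDERS[name]()
    if data_seed is not None:
        problem.data_seed = int(data_seed)
    problem.set_data()
    return problem
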