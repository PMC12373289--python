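"""Transforms, bounds and the penalty function mediating optimiser and model.

A *modification* is a set of binary settings — log transform, scale-factor
transform, parameter bounds, rate bounds — applied in a problem-specific
standard form: the problem defines which parameters are log-transformed,
its sampling box doubles as the parameter bounds, and its list of transition
rates defines the rate bounds.

Rate bounds constrain the *maximum* transition rate over the physiological
voltage range V in [-120, 60] mV so that transitions occur on timescales
between one minute and one microsecond, i.e. rates between 1.67e-5 ms^-1
and 1000 ms^-1.

Bound violations are mapped to a discontinuous penalty of at least 1e5 that
grows with the violation distance; the model is *not* solved for penalised
parameters.  Note the boundary itself is treated as a violation (the
Heaviside convention H(0) = 1), so samplers draw from the open box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chanbench.models import V_RANGE, RateExpression

__all__ = [
    "RATE_LOWER",
    "RATE_UPPER",
    "rate_bounds_from_timescales",
    "Modification",
    "BoundsSpec",
    "max_rate",
    "penalty",
    "penalty_gradient",
    "check_bounds",
    "to_search_space",
    "from_search_space",
    "search_space_bounds",
]

_PENALTY_SCALE = 1e5


def rate_bounds_from_timescales(slowest_ms: float = 60_000.0,
                                fastest_ms: float = 1e-3) -> tuple[float, float]:
    """Rate bounds (ms^-1) from the slowest and fastest admissible timescales.

    One minute and one microsecond give 1.67e-5 and 1000 ms^-1.
    """
    return 1.0 / slowest_ms, 1.0 / fastest_ms


RATE_LOWER, RATE_UPPER = rate_bounds_from_timescales()


@dataclass(frozen=True)
class Modification:
    """Binary optimiser-facing settings plus optimiser hyperparameter overrides."""

    log_transform: bool = False
    scale_transform: bool = False
    parameter_bounds: bool = False
    rate_bounds: bool = False
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class BoundsSpec:
    """Elementwise parameter box and per-rate bounds.

    ``rate_lower``/``rate_upper`` align with a problem's rate-expression
    list; entries default to the global timescale-derived bounds.
    """

    lower: np.ndarray
    upper: np.ndarray
    rate_lower: np.ndarray | None = None
    rate_upper: np.ndarray | None = None

    def __post_init__(self):
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(self.lower >= self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")
        if self.rate_lower is not None:
            self.rate_lower = np.asarray(self.rate_lower, dtype=float)
            self.rate_upper = np.asarray(self.rate_upper, dtype=float)
            if np.any(self.rate_lower >= self.rate_upper):
                raise ValueError("rate lower bounds must be below upper bounds")


def max_rate(rate: RateExpression, params, v_range=V_RANGE, n_grid: int = 181) -> float:
    """Maximum of a transition rate over the physiological voltage range.

    Exponential kinds are monotone in V so the maximum sits at an endpoint
    (both endpoints are checked so the result is also correct for negative
    coefficients); general rates are maximised on a uniform voltage grid.
    """
    params = np.asarray(params, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        if rate.kind == "constant":
            return float(rate(params, 0.0))
        if rate.kind in ("pos_exp", "neg_exp"):
            ends = np.array([float(rate(params, v_range[0])), float(rate(params, v_range[1]))])
            return float(np.max(ends))
        grid = np.linspace(v_range[0], v_range[1], n_grid)
        return float(np.max(rate(params, grid)))


def _violation_terms(params, bounds: BoundsSpec, rates=None,
                     check_params=True, check_rates=True):
    """(distances, labels) for every violated bound; H(0)=1, so touching a
    bound counts as a violation with distance zero."""
    terms = []
    if check_params:
        for i, (p, lo, hi) in enumerate(zip(params, bounds.lower, bounds.upper)):
            if lo - p >= 0:
                terms.append((lo - p, ("param_lower", i)))
            if p - hi >= 0:
                terms.append((p - hi, ("param_upper", i)))
    if check_rates and rates and bounds.rate_lower is not None:
        for j, rate in enumerate(rates):
            r = max_rate(rate, params)
            lo, hi = bounds.rate_lower[j], bounds.rate_upper[j]
            if not np.isfinite(r):
                terms.append((np.inf, ("rate_upper", j)))
                continue
            if lo - r >= 0:
                terms.append((lo - r, ("rate_lower", j)))
            if r - hi >= 0:
                terms.append((r - hi, ("rate_upper", j)))
    return terms


def penalty(params, bounds: BoundsSpec, rates=None,
            check_params=True, check_rates=True) -> float:
    """Discontinuous bound-violation penalty.

    Each violated bound contributes ``1e5 * (1 + ln(1 + d))`` where d >= 0
    is the violation distance (parameter distance, or distance of the
    maximum transition rate from its bound).  Zero iff no bound is violated;
    otherwise at least 1e5.
    """
    params = np.asarray(params, dtype=float)
    terms = _violation_terms(params, bounds, rates, check_params, check_rates)
    if not terms:
        return 0.0
    total = 0.0
    for d, _ in terms:
        total += _PENALTY_SCALE * (1.0 + np.log1p(d)) if np.isfinite(d) else 1e3 * _PENALTY_SCALE
    return float(total)


def penalty_gradient(params, bounds: BoundsSpec, rates=None,
                     check_params=True, check_rates=True) -> np.ndarray:
    """Subgradient of the penalty: zero inside the bounds, the derivative of
    the log terms outside (rate terms by finite differences on max_rate)."""
    params = np.asarray(params, dtype=float)
    grad = np.zeros_like(params)
    terms = _violation_terms(params, bounds, rates, check_params, check_rates)
    for d, (kind, idx) in terms:
        if not np.isfinite(d):
            continue
        scale = _PENALTY_SCALE / (1.0 + d)
        if kind == "param_lower":
            grad[idx] -= scale
        elif kind == "param_upper":
            grad[idx] += scale
        else:
            h = 1e-7 * np.maximum(np.abs(params), 1e-4)
            for j in range(params.size):
                pp = params.copy(); pp[j] += h[j]
                pm = params.copy(); pm[j] -= h[j]
                dr = (max_rate(rates[idx], pp) - max_rate(rates[idx], pm)) / (2 * h[j])
                grad[j] += scale * dr * (1.0 if kind == "rate_upper" else -1.0)
    return grad


def check_bounds(params, modification: Modification, problem):
    """Classify a parameter vector against the effective bounds.

    Returns (in_bounds, violating_terms).  The Staircase problems force both
    bound types on regardless of the modification; that is enforced by the
    problem's ``always_bounded`` flag.
    """
    check_p = modification.parameter_bounds or problem.always_bounded
    check_r = modification.rate_bounds or problem.always_bounded
    if not (check_p or check_r):
        return True, []
    terms = _violation_terms(np.asarray(params, dtype=float), problem.bounds,
                             problem.rate_expressions, check_p, check_r)
    return len(terms) == 0, terms


# ---------------------------------------------------------------------------
# Search-space transforms
# ---------------------------------------------------------------------------

def to_search_space(params, modification: Modification, problem) -> np.ndarray:
    """Map model parameters to the optimiser's search space.

    Scale transform first (p -> p / p*, so the true parameters map to the
    all-ones vector), then log transform on the problem's designated
    parameter subset.  The round trip is exact to floating point.
    """
    x = np.asarray(params, dtype=float).copy()
    if modification.scale_transform:
        x = x / problem.true_parameters
    if modification.log_transform:
        idx = problem.log_indices
        if np.any(x[idx] <= 0):
            raise ValueError("log transform requires positive parameters")
        x[idx] = np.log(x[idx])
    return x


def from_search_space(x, modification: Modification, problem) -> np.ndarray:
    """Inverse of :func:`to_search_space`."""
    p = np.asarray(x, dtype=float).copy()
    if modification.log_transform:
        idx = problem.log_indices
        p[idx] = np.exp(p[idx])
    if modification.scale_transform:
        p = p * problem.true_parameters
    return p


def search_gradient_factor(params, modification: Modification, problem) -> np.ndarray:
    """dp/dx evaluated at the given model-space parameters (diagonal chain
    factor for transforming cost gradients into search space)."""
    params = np.asarray(params, dtype=float)
    fac = np.ones_like(params)
    if modification.log_transform:
        idx = problem.log_indices
        scaled = params / problem.true_parameters if modification.scale_transform else params
        fac[idx] = scaled[idx]
    if modification.scale_transform:
        fac = fac * problem.true_parameters
    return fac


def search_space_bounds(modification: Modification, problem):
    """The problem's parameter box mapped into search space (both transforms
    are monotone increasing for positive parameters, so the box maps to a box)."""
    lo = to_search_space(problem.bounds.lower, modification, problem)
    hi = to_search_space(problem.bounds.upper, modification, problem)
    return np.minimum(lo, hi), np.maximum(lo, hi)
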