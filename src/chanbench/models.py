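"""Kinetic schemes for voltage-gated ion channels.

Two model classes are supported:

* :class:`HHModel` -- Hodgkin-Huxley formulations, where the open probability
  is a product of independent gating variables, each following a first-order
  relaxation with voltage-dependent steady state and time constant.
* :class:`MarkovModel` -- Markov-state formulations, a linear ODE over
  conformational-state occupancies with voltage-dependent transition rates.

Transition rates are most commonly of the form ``A*exp(b*V)`` or
``A*exp(-b*V)`` (units ms^-1, voltage mV); arbitrary voltage dependence is
supported through the ``general`` kind.  Model parameters are addressed by
index into a flat parameter vector, so that the same expressions serve both
simulation and the rate-bound machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "V_RANGE",
    "RateExpression",
    "RateGate",
    "ExplicitGate",
    "HHModel",
    "MarkovModel",
]

# Physiological voltage range (mV) over which rate bounds are assessed.
V_RANGE = (-120.0, 60.0)


def _resolve(ref, params):
    """A rate coefficient is either a parameter index (int) or a fixed float."""
    if isinstance(ref, (int, np.integer)):
        return params[ref]
    return ref


@dataclass(frozen=True)
class RateExpression:
    """A voltage-dependent transition rate r(p, V) in ms^-1.

    kind:
        ``pos_exp``  -> A * exp(+b * V)
        ``neg_exp``  -> A * exp(-b * V)
        ``constant`` -> A
        ``general``  -> ``func(params, V)``
    ``A`` and ``b`` may be parameter indices (int) or fixed values (float).
    For the exponential kinds with non-negative A and b the rate is
    non-negative over the whole voltage range.
    """

    kind: str
    A: int | float | None = None
    b: int | float | None = None
    func: Callable | None = None

    def __post_init__(self):
        if self.kind not in ("pos_exp", "neg_exp", "constant", "general"):
            raise ValueError(f"unknown rate kind {self.kind!r}")
        if self.kind == "general" and self.func is None:
            raise ValueError("general rates require func")

    def __call__(self, params, V):
        params = np.asarray(params, dtype=float)
        if self.kind == "general":
            return self.func(params, V)
        A = _resolve(self.A, params)
        if self.kind == "constant":
            return A * np.ones_like(np.asarray(V, dtype=float))
        b = _resolve(self.b, params)
        sign = 1.0 if self.kind == "pos_exp" else -1.0
        with np.errstate(over="ignore"):
            return A * np.exp(sign * b * np.asarray(V, dtype=float))


class RateGate:
    """HH gate defined by opening rate alpha and closing rate beta.

    dx/dt = alpha*(1-x) - beta*x, so x_inf = alpha/(alpha+beta) and
    tau = 1/(alpha+beta).
    """

    def __init__(self, alpha: RateExpression, beta: RateExpression, exponent: int = 1):
        self.alpha = alpha
        self.beta = beta
        self.exponent = int(exponent)
        self.instantaneous = False

    def steady_state(self, params, V):
        a = self.alpha(params, V)
        b = self.beta(params, V)
        return a / (a + b)

    def time_constant(self, params, V):
        return 1.0 / (self.alpha(params, V) + self.beta(params, V))


class ExplicitGate:
    """HH gate given directly by steady state and time constant callables.

    ``instantaneous`` gates equilibrate immediately (x = x_inf(V)); they carry
    no ODE state.
    """

    def __init__(self, x_inf, tau=None, exponent: int = 1, instantaneous: bool = False):
        if tau is None and not instantaneous:
            raise ValueError("non-instantaneous gates require a time constant")
        self._x_inf = x_inf
        self._tau = tau
        self.exponent = int(exponent)
        self.instantaneous = bool(instantaneous)

    def steady_state(self, params, V):
        return self._x_inf(np.asarray(params, dtype=float), V)

    def time_constant(self, params, V):
        if self.instantaneous:
            raise ValueError("instantaneous gate has no time constant")
        return self._tau(np.asarray(params, dtype=float), V)


@dataclass
class HHModel:
    """Hodgkin-Huxley channel model.

    I(t) = g(p, V) * prod_i x_i(t)^{e_i} * (V - E_rev)

    ``conductance`` is either a parameter index (constant conductance) or a
    callable ``g(params, V)`` for voltage-dependent maximal conductance.
    ``rates`` lists the transition-rate expressions subject to rate bounds.
    """

    gates: Sequence
    conductance: int | Callable
    E_rev: float
    n_parameters: int
    rates: Sequence[RateExpression] = field(default_factory=list)
    name: str = "hh"

    def conductance_value(self, params, V):
        if callable(self.conductance):
            return self.conductance(np.asarray(params, dtype=float), V)
        return params[self.conductance]

    @property
    def dynamic_gates(self):
        return [g for g in self.gates if not g.instantaneous]

    def current(self, params, V, gate_values):
        """Current from per-gate open probabilities.

        ``gate_values`` must contain one entry per gate (dynamic and
        instantaneous), in gate order.
        """
        po = 1.0
        for g, x in zip(self.gates, gate_values):
            po = po * x**g.exponent
        return self.conductance_value(params, V) * po * (V - self.E_rev)


@dataclass
class MarkovModel:
    """Markov-state channel model.

    dx/dt = Q(p, V) x with occupancies x summing to one;
    I = g * x_open * (V - E_rev).
    """

    n_states: int
    transitions: Sequence[tuple]  # (from_state, to_state, RateExpression)
    open_index: int
    conductance: int
    E_rev: float
    n_parameters: int
    name: str = "markov"

    @property
    def rates(self):
        return [r for (_, _, r) in self.transitions]

    def rate_matrix(self, params, V):
        """Generator matrix Q at a fixed voltage; columns sum to zero."""
        Q = np.zeros((self.n_states, self.n_states))
        for i, j, rate in self.transitions:
            r = float(rate(params, V))
            Q[j, i] += r
            Q[i, i] -= r
        return Q

    def steady_state(self, params, V):
        """Equilibrium occupancy at voltage V (null space of Q, normalised)."""
        Q = self.rate_matrix(params, V)
        A = np.vstack([Q, np.ones(self.n_states)])
        b = np.zeros(self.n_states + 1)
        b[-1] = 1.0
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        x = np.clip(x, 0.0, None)
        s = x.sum()
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError("degenerate steady state")
        return x / s

    def current(self, params, V, occupancy_open):
        return params[self.conductance] * occupancy_open * (V - self.E_rev)
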