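"""Success cost thresholds from one-at-a-time cost slices.

A successful optimisation is one that drives the cost below a
problem-specific threshold.  The threshold is derived from
profile-likelihood-style slices of the cost: each parameter in turn is
perturbed by up to +/-5% of its true value (others held at truth), and the
threshold is the minimum cost observed at the +/-5% endpoints over the
parameters deemed identifiable.  Parameters with flat slices or a
noise-shifted minimum can be excluded via an explicit index list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CostSlice", "cost_slices", "cost_threshold", "slices_to_frame"]


@dataclass
class CostSlice:
    """Cost along a one-parameter perturbation around the true parameters."""

    parameter_index: int
    perturbations: np.ndarray  # fractional, e.g. -0.05 .. 0.05
    costs: np.ndarray          # NaN where the simulation failed
    identifiable: bool = True


def cost_slices(problem, grid=None) -> list[CostSlice]:
    """One slice per parameter on a +/-5% grid in 1% steps (default).

    The slice value at zero perturbation equals the cost at the true
    parameters.  Evaluations bypass any attached tracker.
    """
    if grid is None:
        grid = np.arange(-5, 6) / 100.0
    grid = np.asarray(grid, dtype=float)
    p_star = problem.true_parameters
    tracker, term = problem.tracker, problem.termination
    problem.tracker, problem.termination = None, None
    try:
        slices = []
        for i in range(problem.n_parameters):
            costs = np.empty(grid.size)
            for k, f in enumerate(grid):
                p = p_star.copy()
                p[i] = p_star[i] * (1.0 + f)
                try:
                    costs[k] = problem.cost(p)
                except (ValueError, FloatingPointError):
                    costs[k] = np.nan
            slices.append(CostSlice(i, grid.copy(), costs))
    finally:
        problem.tracker, problem.termination = tracker, term
    return slices


def cost_threshold(slices, excluded=()) -> float:
    """Minimum endpoint cost over the non-excluded slices.

    The endpoints are the extreme perturbations of each slice (+/-5% on the
    default grid).  Failed endpoints are ignored.
    """
    excluded = set(excluded)
    endpoint_costs = []
    for s in slices:
        if s.parameter_index in excluded:
            continue
        lo = s.costs[np.argmin(s.perturbations)]
        hi = s.costs[np.argmax(s.perturbations)]
        for c in (lo, hi):
            if np.isfinite(c):
                endpoint_costs.append(c)
    if not endpoint_costs:
        raise ValueError("no identifiable slices left to derive a threshold from")
    return float(min(endpoint_costs))


def slices_to_frame(slices) -> pd.DataFrame:
    rows = []
    for s in slices:
        for f, c in zip(s.perturbations, s.costs):
            rows.append({"parameter": s.parameter_index, "perturbation": f, "cost": c})
    return pd.DataFrame(rows)
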