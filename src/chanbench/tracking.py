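"""Per-evaluation bookkeeping, termination rules and run summaries.

Every parameter vector an optimiser attempts is recorded: whether it was
inside the bounds, whether the model was actually solved (penalised points
are not model solves), whether sensitivities were requested (gradient
solves are more expensive and counted separately), the cost including any
penalty, and the running best.  Termination is checked at every evaluation:

* success -- best cost has dropped below the problem's cost threshold;
* stagnation -- the best cost improved by less than 1e-7 over the last
  2500 model solves (penalty evaluations do not advance the window);
* max_evaluations -- a hard cap on model solves, set very large so that it
  rarely triggers.

Gradient solves are converted into equivalent plain function evaluations
(FEs) through a problem-specific time ratio when a run is summarised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationRecord",
    "TerminationSpec",
    "RunResult",
    "Tracker",
    "Terminated",
    "run_results_to_frame",
]


class Terminated(Exception):
    """Raised by the harness when a termination criterion fires mid-run."""

    def __init__(self, status: str):
        self.status = status
        super().__init__(status)


@dataclass
class EvaluationRecord:
    params: np.ndarray
    in_bounds: bool
    solved: bool
    with_sensitivities: bool
    cost: float
    best_cost: float = np.inf
    wall_time: float = 0.0


@dataclass
class TerminationSpec:
    """Termination settings shared across approaches."""

    cost_threshold: float
    stagnation_window: int = 2500
    improvement_epsilon: float = 1e-7
    max_iterations: int = 25_000
    max_model_solves: int | None = None
    wall_clock_cap: float | None = None  # seconds; off by default

    def __post_init__(self):
        if self.stagnation_window <= 0 or self.improvement_epsilon <= 0:
            raise ValueError("termination settings must be positive")
        if self.max_iterations <= 0:
            raise ValueError("termination settings must be positive")


@dataclass
class RunResult:
    """Outcome of a single optimisation run."""

    success: bool
    status: str
    cost_solves: int
    grad_solves: int
    out_of_bounds: int
    best_cost: float
    best_params: np.ndarray | None
    time_ratio: float = 1.0

    @property
    def fe_time(self) -> float:
        """Run time converted into plain function evaluations."""
        return self.cost_solves + self.time_ratio * self.grad_solves

    def to_dict(self):
        d = {
            "success": bool(self.success),
            "status": self.status,
            "cost_solves": int(self.cost_solves),
            "grad_solves": int(self.grad_solves),
            "out_of_bounds": int(self.out_of_bounds),
            "best_cost": float(self.best_cost),
            "time_ratio": float(self.time_ratio),
            "fe_time": float(self.fe_time),
            "best_params": None if self.best_params is None
            else [float(v) for v in self.best_params],
        }
        return d

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d):
        bp = d.get("best_params")
        return cls(
            success=bool(d["success"]), status=d["status"],
            cost_solves=int(d["cost_solves"]), grad_solves=int(d["grad_solves"]),
            out_of_bounds=int(d["out_of_bounds"]), best_cost=float(d["best_cost"]),
            best_params=None if bp is None else np.asarray(bp, dtype=float),
            time_ratio=float(d.get("time_ratio", 1.0)),
        )


class Tracker:
    """Ledger of one optimisation run.

    ``record`` updates the counters and the running best; the best cost is
    non-increasing by construction.  ``check_termination`` classifies the
    current state and is consulted after every evaluation.
    """

    def __init__(self, keep_records: bool = True):
        self.keep_records = keep_records
        self.records: list[EvaluationRecord] = []
        self.cost_solves = 0
        self.grad_solves = 0
        self.out_of_bounds = 0
        self.best_cost = np.inf
        self.best_params = None
        # best cost after each model solve, for the stagnation window
        self._best_per_solve: list[float] = []

    @property
    def model_solves(self) -> int:
        return self.cost_solves + self.grad_solves

    def record(self, rec: EvaluationRecord) -> None:
        if rec.solved:
            if rec.with_sensitivities:
                self.grad_solves += 1
            else:
                self.cost_solves += 1
        if not rec.in_bounds:
            self.out_of_bounds += 1
        if np.isfinite(rec.cost) and rec.cost < self.best_cost:
            self.best_cost = float(rec.cost)
            self.best_params = np.array(rec.params, dtype=float)
        rec.best_cost = self.best_cost
        if rec.solved:
            self._best_per_solve.append(self.best_cost)
        if self.keep_records:
            self.records.append(rec)

    def check_termination(self, spec: TerminationSpec) -> str:
        """One of 'running', 'success', 'stagnated', 'max_evaluations'."""
        if self.best_cost < spec.cost_threshold:
            return "success"
        w = spec.stagnation_window
        h = self._best_per_solve
        if len(h) >= w and h[-w] - h[-1] < spec.improvement_epsilon:
            return "stagnated"
        cap = spec.max_model_solves
        if cap is not None and self.model_solves >= cap:
            return "max_evaluations"
        return "running"

    def summarise(self, spec: TerminationSpec, time_ratio: float = 1.0,
                  status: str | None = None) -> RunResult:
        status = status or self.check_termination(spec)
        if status == "running":
            status = "optimiser_converged"
        return RunResult(
            success=self.best_cost < spec.cost_threshold,
            status=status,
            cost_solves=self.cost_solves,
            grad_solves=self.grad_solves,
            out_of_bounds=self.out_of_bounds,
            best_cost=self.best_cost,
            best_params=self.best_params,
            time_ratio=time_ratio,
        )


def run_results_to_frame(results, **extra) -> pd.DataFrame:
    """Summary table with one row per run (the analysis layer's input)."""
    rows = []
    for i, r in enumerate(results):
        row = {"run": i, "success": r.success, "status": r.status,
               "cost_solves": r.cost_solves, "grad_solves": r.grad_solves,
               "out_of_bounds": r.out_of_bounds, "best_cost": r.best_cost,
               "time_ratio": r.time_ratio, "fe_time": r.fe_time}
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)
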