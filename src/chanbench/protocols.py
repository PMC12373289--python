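"""Piecewise-constant voltage-clamp protocols.

A protocol is an ordered list of (duration, voltage) steps plus the times at
which the simulated current is sampled.  Holding the command voltage constant
within each step is what makes the analytic per-step solvers exact; published
protocols containing ramps are approximated by short sub-steps before being
loaded here.  Units: time in ms, voltage in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VoltageProtocol"]


@dataclass(frozen=True)
class VoltageProtocol:
    """An ordered sequence of constant-voltage steps with sampling times.

    Parameters
    ----------
    durations : array of float
        Step durations in ms; all strictly positive.
    voltages : array of float
        Command voltage of each step in mV.
    sampling_times : array of float
        Strictly increasing times (ms, measured from the start of the
        protocol) at which the current is recorded.  The last sampling time
        must not exceed the total protocol duration.
    """

    durations: np.ndarray
    voltages: np.ndarray
    sampling_times: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.durations, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        t = np.asarray(self.sampling_times, dtype=float)
        if d.ndim != 1 or v.ndim != 1 or d.size != v.size or d.size == 0:
            raise ValueError("durations and voltages must be equal-length 1-D arrays")
        if np.any(d <= 0):
            raise ValueError("step durations must be strictly positive")
        if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be a strictly increasing 1-D array")
        if t[0] < 0 or t[-1] > d.sum() + 1e-12:
            raise ValueError("sampling times must lie within the protocol duration")
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "sampling_times", t)

    @property
    def n_steps(self) -> int:
        return self.durations.size

    @property
    def total_duration(self) -> float:
        return float(self.durations.sum())

    @property
    def step_starts(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.durations)[:-1]))

    def voltage_at(self, t):
        """Command voltage at time(s) ``t`` (right-continuous at step edges)."""
        edges = np.cumsum(self.durations)
        idx = np.minimum(np.searchsorted(edges, t, side="right"), self.n_steps - 1)
        return self.voltages[idx]

    def steps_with_samples(self):
        """Yield (t_start, duration, voltage, local_sample_times, sample_indices).

        ``local_sample_times`` are measured from the start of the step.  A
        sample falling exactly on a step boundary belongs to the later step.
        """
        starts = self.step_starts
        edges = np.cumsum(self.durations)
        t = self.sampling_times
        for k in range(self.n_steps):
            lo, hi = starts[k], edges[k]
            if k == self.n_steps - 1:
                mask = (t >= lo) & (t <= hi + 1e-12)
            else:
                mask = (t >= lo) & (t < hi)
            idx = np.nonzero(mask)[0]
            yield lo, self.durations[k], self.voltages[k], t[idx] - lo, idx

    @classmethod
    def from_steps(cls, steps, dt: float) -> "VoltageProtocol":
        """Build a protocol from (duration, voltage) pairs with uniform sampling.

        Samples are placed at 0, dt, 2*dt, ... up to the total duration.
        """
        durations = np.array([s[0] for s in steps], dtype=float)
        voltages = np.array([s[1] for s in steps], dtype=float)
        total = durations.sum()
        n = int(np.floor(total / dt + 1e-9))
        times = np.arange(n + 1) * dt
        times = times[times <= total + 1e-12]
        return cls(durations, voltages, times)

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, steps_path, samples_path=None) -> None:
        pd.DataFrame(
            {"duration_ms": self.durations, "voltage_mV": self.voltages}
        ).to_csv(steps_path, index=False)
        if samples_path is not None:
            pd.DataFrame({"time_ms": self.sampling_times}).to_csv(
                samples_path, index=False
            )

    @classmethod
    def from_csv(cls, steps_path, samples_path=None, dt: float | None = None):
        steps = pd.read_csv(steps_path)
        durations = steps["duration_ms"].to_numpy(dtype=float)
        voltages = steps["voltage_mV"].to_numpy(dtype=float)
        if samples_path is not None:
            times = pd.read_csv(samples_path)["time_ms"].to_numpy(dtype=float)
        elif dt is not None:
            return cls.from_steps(list(zip(durations, voltages)), dt)
        else:
            raise ValueError("provide either samples_path or a uniform dt")
        return cls(durations, voltages, times)
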