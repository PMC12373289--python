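# chanbench

Benchmarking of optimisation strategies for cardiac ion-channel models.

Fitting a kinetic channel model to voltage-clamp data is a deceptively hard
optimisation problem: the open state is the only observable, parameters are
often poorly identified, the dynamics mix microsecond and second
timescales, and the data may be noisy. Dozens of optimisation approaches
have been published for exactly this task, with little basis for choosing
between them. `chanbench` provides a standard test bed for that choice: a
suite of simulated channel-fitting problems, a harness that runs published
optimisation approaches under identical conditions while counting every
model evaluation, and the statistics needed to compare them fairly.

## What is in the box

**Problems.** Five benchmark problems plus a fast test fixture, each a
black box exposing `cost(p)`, `gradient(p)` and a seeded initial-guess
sampler. They cover IKr, IKur and INa kinetics, Hodgkin–Huxley and Markov
formulations, trace-RMSE and summary-statistic costs, noisy and noise-free
data, and 9–25 parameters:

| name | model | parameters | cost | noise |
|---|---|---|---|---|
| `staircase_hh` | IKr, 2-gate HH | 9 | trace RMSE | yes |
| `staircase_mm` | IKr, 5-state Markov | 15 | trace RMSE | yes |
| `loewe_ikr` | IKr, Courtemanche-style HH | 12 | trace RMSE | no |
| `loewe_ikur` | IKur, Courtemanche-style HH | 25 | trace RMSE | no |
| `moreno_ina` | INa, 5-state Markov | 16 | summary statistics | no |
| `fixture_hh` | 1-gate toy | 3 | trace RMSE | no |

**Approaches.** An *approach* pairs an optimiser (Nelder–Mead, CMA-ES,
trust-region-reflective least squares, particle swarm, genetic algorithm,
…) with a *modification*: binary settings for log transforms, scale-factor
transforms, parameter bounds and transition-rate bounds. The registry
reconstructs 42 published approaches from 30 studies; a core optimiser set
covering all six algorithm families is runnable, the rest are registry
entries. Rate bounds constrain the fastest transition over
V ∈ [−120, 60] mV to timescales between 1 µs and 1 min
(1.67×10⁻⁵–10³ ms⁻¹); violations of any enabled bound are mapped to a
discontinuous penalty of at least 10⁵ *without* solving the model.

**Tracking and statistics.** Every proposed parameter vector is recorded:
in/out of bounds, solved with or without sensitivities, cost, running
best. A run succeeds when its cost drops below a problem-specific
threshold derived from ±5% one-at-a-time cost slices around the true
parameters. Approaches are ranked by Expected Run Time in function
evaluations (FEs),

    ERT = T_s + T_f · (1 − p̂) / p̂,

where T_s, T_f are mean successful/failed run times and p̂ the success
fraction; gradient solves convert to FEs through a per-problem time ratio.
Significance comes from a bootstrap in which the success rate is drawn
from the Jeffreys posterior Beta(x + ½, nRun − x + ½) — so even an
approach that failed every observed run gets a finite, comparable ERT
distribution — and two approaches differ significantly when one is better
in ≥95% of all pairwise sample comparisons.

**A multistart recommendation.** The package includes a multistart
approach built from the benchmark's strongest ingredients:
trust-region-reflective least squares with parameter bounds, plus log
transforms and rate bounds, restarted from fresh sampled guesses until
success (`chanbench.run_new_approach`, or `--approach new` on the CLI).

## Worked example

Run the bounded-TRR reference approach and the multistart variant on the
fixture problem from ten shared starting points, then compare:

```bash
$ chanbench run --problem fixture_hh --approach plain-trr --approach new \
      --n-runs 10 --seed 4 --out demo
BoundedTRR: 10/10 successful runs (summary in demo/fixture_hh_BoundedTRR_summary.csv)
MultistartTRR: 10/10 successful runs (summary in demo/fixture_hh_MultistartTRR_summary.csv)

$ chanbench analyse --summary demo/fixture_hh_BoundedTRR_summary.csv \
      --summary demo/fixture_hh_MultistartTRR_summary.csv --seed 0
                approach  n_run  successes  p_hat  T_s  T_f  ERT  ERT_boot_median best_significantly_better  p_hat_vs_best
fixture_hh/MultistartTRR     10         10    1.0 25.0  NaN 25.0        26.054069                                      NaN
   fixture_hh/BoundedTRR     10         10    1.0 33.7  NaN 33.7        34.853503                                 0.126215
```

Both approaches succeed on every run here (the fixture is easy), but the
log-transformed variant needs fewer function evaluations per run
(T_s = 25.0 vs 33.7 FEs), so its expected run time is lower. The
`p_hat_vs_best` column is the fraction of bootstrap comparisons the slower
approach wins: 0.13 > 0.05, so ten runs are not yet enough to call the
difference significant — exactly the situation the head-to-head routine
(`chanbench.head_to_head`) resolves by adding batches of shared starts
until one side wins 95% of comparisons.

The same workflow in Python:

```python
import chanbench as cb

problem = cb.build_problem("loewe_ikr")          # noise-free IKr problem
print(problem.cost(problem.true_parameters))     # 0.0 — data generated at truth

result = cb.run_new_approach(problem, max_restarts=20, seed=1)
print(result.success, result.n_restarts, result.total_fe_time)
```

## Layout

```
src/chanbench/
  protocols.py      voltage-clamp step protocols
  models.py         HH-gate and Markov kinetic schemes
  solvers.py        analytic, adaptive-ODE and sensitivity solvers
  catalogue.py      built-in problem definitions (models, protocols, truths)
  problems.py       the BenchmarkProblem black box + sampling
  modifications.py  transforms, bounds, penalty function
  tracking.py       per-evaluation ledger, termination, run summaries
  optimisers/       approach registry, optimiser runners, multistart TRR
  analysis.py       ERT, time ratios, bootstrap significance, head-to-head
  thresholds.py     cost slices and success thresholds
  cli.py            chanbench run / analyse / thresholds / fixture
docs/methods.md     modelling and statistical methods in detail
```
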