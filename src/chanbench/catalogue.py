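"""Built-in model, protocol and parameter definitions for the benchmark suite.

The five benchmark problems cover IKr, IKur and INa channels in both
Hodgkin-Huxley and Markov formulations, with trace-based and
summary-statistic costs, noisy and noise-free data, and 9 to 25 parameters.

Model structures and parameter values follow the published source models
where those are available (the 9-parameter two-gate IKr Hodgkin-Huxley
model and its cell-specific parameters; Courtemanche-style IKr/IKur gate
kinetics); the remaining schemes are constructed to the documented
parameter counts and kinetic ranges and are labelled approximations in the
methods note.  The staircase protocol used here is a step-only
approximation of the published information-rich staircase.

Units: ms, mV, ms^-1, conductances in mS, currents in nA conventions.
"""

from __future__ import annotations

import numpy as np

from chanbench.models import (
    ExplicitGate,
    HHModel,
    MarkovModel,
    RateExpression,
    RateGate,
)
from chanbench.modifications import RATE_LOWER, RATE_UPPER
from chanbench.protocols import VoltageProtocol
from chanbench.solvers import SolverSettings

__all__ = ["BUILDERS", "staircase_protocol", "loewe_protocols", "moreno_summary_spec",
           "RATE_LOWER", "RATE_UPPER", "COST_THRESHOLDS"]

# Success thresholds computed once from the +/-5% one-at-a-time cost slices
# (minimum endpoint cost over identifiable parameters) on the default data;
# see chanbench.thresholds for the procedure.  The Moreno conductance is
# excluded as unidentifiable: every biomarker there is a normalised ratio,
# so uniform current scaling leaves the cost unchanged.
COST_THRESHOLDS = {
    "staircase_hh": 0.0157333,
    "staircase_mm": 0.00579997,
    "loewe_ikr": 0.000199522,
    "loewe_ikur": 1.84328e-05,
    "moreno_ina": 0.00417111,
    "fixture_hh": 0.239041,
}

# Parameters excluded from the threshold derivation as unidentifiable.
THRESHOLD_EXCLUSIONS = {"moreno_ina": [15]}

# FE-equivalent cost of one gradient solve relative to one cost solve,
# fixed per problem as part of the benchmark configuration.
TIME_RATIOS = {
    "staircase_hh": 8.77,
    "staircase_mm": 13.3,
    "loewe_ikr": 10.5,
    "loewe_ikur": 26.0,
    "moreno_ina": 17.0,
    "fixture_hh": 4.0,
}

N_RUN_DEFAULTS = {
    "staircase_hh": 10,
    "staircase_mm": 50,
    "loewe_ikr": 10,
    "loewe_ikur": 100,
    "moreno_ina": 10,
    "fixture_hh": 10,
}

# Noise scaled so the RMSE cost at the true parameters sits at the
# documented per-problem level.
NOISE_SIGMA = {"staircase_hh": 0.01558, "staircase_mm": 0.005767}


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def staircase_protocol(dt: float = 1.0) -> VoltageProtocol:
    """Step-only approximation of the information-rich staircase protocol:
    a leak/holding prelude, ascending 20 mV staircase with intermediate
    down-steps, and a repolarising tail."""
    steps = [(250.0, -80.0), (50.0, -120.0), (400.0, -80.0)]
    for V in (-60.0, -40.0, -20.0, 0.0, 20.0, 40.0):
        steps.append((500.0, V))
        steps.append((500.0, V - 20.0))
    steps += [(100.0, -120.0), (250.0, -80.0)]
    return VoltageProtocol.from_steps(steps, dt)


def loewe_protocols(dt: float = 2.0):
    """Simple low-information activation step family: hold, test step,
    tail at -40 mV, return to holding."""
    protos = []
    for Vt in (-40.0, -20.0, 0.0, 20.0, 40.0):
        steps = [(500.0, -80.0), (1000.0, Vt), (500.0, -40.0), (200.0, -80.0)]
        protos.append(VoltageProtocol.from_steps(steps, dt))
    return protos


# ---------------------------------------------------------------------------
# Staircase HH: 9-parameter two-gate IKr model
# ---------------------------------------------------------------------------

STAIRCASE_HH_TRUE = np.array([
    2.26e-4, 0.0699,    # k1 = p1 exp(+p2 V)   activation opening
    3.45e-5, 0.05462,   # k2 = p3 exp(-p4 V)   activation closing
    0.0873, 8.91e-3,    # k3 = p5 exp(+p6 V)   inactivation
    5.15e-3, 0.03158,   # k4 = p7 exp(-p8 V)   recovery
    0.1524,             # conductance
])


def _staircase_hh_model() -> HHModel:
    k1 = RateExpression("pos_exp", A=0, b=1)
    k2 = RateExpression("neg_exp", A=2, b=3)
    k3 = RateExpression("pos_exp", A=4, b=5)
    k4 = RateExpression("neg_exp", A=6, b=7)
    gates = [RateGate(k1, k2), RateGate(k4, k3)]  # activation a, recovery r
    return HHModel(gates=gates, conductance=8, E_rev=-88.0, n_parameters=9,
                   rates=[k1, k2, k3, k4], name="staircase_hh")


def _staircase_sampling(n_params, a_indices, b_indices, g_index):
    """Broad Clerx-style region: A-type coefficients log-uniform over the
    admissible decade span, exponential slopes uniform, conductance
    log-uniform a decade either side of truth; samples rejected against the
    rate bounds."""
    from chanbench.problems import SamplingSpec

    kinds = [None] * n_params
    for i in a_indices:
        kinds[i] = ("log_box", 1e-7, 1e3)
    for i in b_indices:
        kinds[i] = ("box", 1e-7, 0.4)
    kinds[g_index] = ("log_factor", 0.1, 10.0)
    return SamplingSpec(kinds, reject_rate_bounds=True)


def _build_staircase_hh():
    from chanbench.problems import BenchmarkProblem

    model = _staircase_hh_model()
    return BenchmarkProblem(
        name="staircase_hh", model=model, protocols=[staircase_protocol()],
        true_parameters=STAIRCASE_HH_TRUE, solver="ode",
        sampling=_staircase_sampling(9, [0, 2, 4, 6], [1, 3, 5, 7], 8),
        log_indices=[0, 2, 4, 6, 8],
        cost_threshold=COST_THRESHOLDS["staircase_hh"],
        n_run_default=N_RUN_DEFAULTS["staircase_hh"],
        time_ratio=TIME_RATIOS["staircase_hh"], data_seed=20201,
        noise_sigma=NOISE_SIGMA["staircase_hh"], always_bounded=True,
        solver_settings=SolverSettings(abs_tol=1e-8, rel_tol=1e-8),
    )


# ---------------------------------------------------------------------------
# Staircase MM: 15-parameter five-state IKr Markov model
# C3 <-> C2 <-> C1 <-> O <-> I
# ---------------------------------------------------------------------------

STAIRCASE_MM_TRUE = np.array([
    2.6e-3, 0.04,    # C3->C2
    4.0e-3, 0.05,    # C2->C3
    0.02,            # C2->C1 (voltage independent)
    0.04,            # C1->C2 (voltage independent)
    0.02, 0.02,      # C1->O
    0.013, 0.03,     # O->C1
    0.09, 0.009,     # O->I
    5.0e-3, 0.03,    # I->O
    0.1524,          # conductance
])


def _staircase_mm_model() -> MarkovModel:
    C3, C2, C1, O, I = range(5)
    transitions = [
        (C3, C2, RateExpression("pos_exp", A=0, b=1)),
        (C2, C3, RateExpression("neg_exp", A=2, b=3)),
        (C2, C1, RateExpression("constant", A=4)),
        (C1, C2, RateExpression("constant", A=5)),
        (C1, O, RateExpression("pos_exp", A=6, b=7)),
        (O, C1, RateExpression("neg_exp", A=8, b=9)),
        (O, I, RateExpression("pos_exp", A=10, b=11)),
        (I, O, RateExpression("neg_exp", A=12, b=13)),
    ]
    return MarkovModel(n_states=5, transitions=transitions, open_index=O,
                       conductance=14, E_rev=-88.0, n_parameters=15,
                       name="staircase_mm")


def _build_staircase_mm():
    from chanbench.problems import BenchmarkProblem

    model = _staircase_mm_model()
    a_idx = [0, 2, 4, 5, 6, 8, 10, 12]
    b_idx = [1, 3, 7, 9, 11, 13]
    return BenchmarkProblem(
        name="staircase_mm", model=model, protocols=[staircase_protocol()],
        true_parameters=STAIRCASE_MM_TRUE, solver="ode",
        sampling=_staircase_sampling(15, a_idx, b_idx, 14),
        log_indices=a_idx + [14],
        cost_threshold=COST_THRESHOLDS["staircase_mm"],
        n_run_default=N_RUN_DEFAULTS["staircase_mm"],
        time_ratio=TIME_RATIOS["staircase_mm"], data_seed=20202,
        noise_sigma=NOISE_SIGMA["staircase_mm"], always_bounded=True,
        solver_settings=SolverSettings(abs_tol=1e-8, rel_tol=1e-8),
    )


# ---------------------------------------------------------------------------
# Loewe IKr: 12-parameter Courtemanche-style HH model
# ---------------------------------------------------------------------------

LOEWE_IKR_TRUE = np.array([
    3.0e-4, 14.1, 5.0,        # alpha_xr
    7.3898e-5, 3.3328, 5.1237,  # beta_xr
    1.0,                      # tau scale
    14.1, 6.5,                # xr steady state
    15.0, 22.4,               # instantaneous rectification gate
    0.0294,                   # conductance
])


def _safe_lin_over_expm1(scale, u, s):
    """scale * u / (1 - exp(-u/s)) with its limit scale*s at u -> 0."""
    u = np.asarray(u, dtype=float)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        denom = -np.expm1(-u / s)
        val = np.where(np.abs(u) < 1e-10 * np.abs(s), scale * s, scale * u / denom)
    return val


def _loewe_ikr_alpha(p, V):
    return _safe_lin_over_expm1(p[0], np.asarray(V, float) + p[1], p[2])


def _loewe_ikr_beta(p, V):
    u = np.asarray(V, dtype=float) - p[4]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        denom = np.expm1(u / p[5])
        val = np.where(np.abs(u) < 1e-10 * np.abs(p[5]), p[3] * p[5], p[3] * u / denom)
    return val


def _loewe_ikr_model() -> HHModel:
    def xr_inf(p, V):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + p[7]) / p[8]))

    def xr_tau(p, V):
        return 1.0 / (p[6] * (_loewe_ikr_alpha(p, V) + _loewe_ikr_beta(p, V)))

    def r_inf(p, V):
        return 1.0 / (1.0 + np.exp((np.asarray(V, float) + p[9]) / p[10]))

    gates = [ExplicitGate(xr_inf, xr_tau), ExplicitGate(r_inf, instantaneous=True)]
    rates = [
        RateExpression("general", func=lambda p, V: p[6] * _loewe_ikr_alpha(p, V)),
        RateExpression("general", func=lambda p, V: p[6] * _loewe_ikr_beta(p, V)),
    ]
    return HHModel(gates=gates, conductance=11, E_rev=-88.0, n_parameters=12,
                   rates=rates, name="loewe_ikr")


LOEWE_IKR_MULTIPLICATIVE = [0, 2, 3, 5, 6, 8, 10, 11]
LOEWE_IKR_ADDITIVE = [1, 4, 7, 9]


def _loewe_sampling(n_params, multiplicative, additive):
    from chanbench.problems import SamplingSpec

    kinds = [None] * n_params
    for i in multiplicative:
        kinds[i] = ("log_factor", 0.1, 10.0)
    for i in additive:
        kinds[i] = ("offset", 60.0)
    return SamplingSpec(kinds)


def _build_loewe_ikr():
    from chanbench.problems import BenchmarkProblem

    return BenchmarkProblem(
        name="loewe_ikr", model=_loewe_ikr_model(), protocols=loewe_protocols(),
        true_parameters=LOEWE_IKR_TRUE, solver="hh_analytic",
        sampling=_loewe_sampling(12, LOEWE_IKR_MULTIPLICATIVE, LOEWE_IKR_ADDITIVE),
        log_indices=LOEWE_IKR_MULTIPLICATIVE,
        cost_threshold=COST_THRESHOLDS["loewe_ikr"],
        n_run_default=N_RUN_DEFAULTS["loewe_ikr"],
        time_ratio=TIME_RATIOS["loewe_ikr"], data_seed=20203,
    )


# ---------------------------------------------------------------------------
# Loewe IKur: 25-parameter Courtemanche-style HH model
# ---------------------------------------------------------------------------

LOEWE_IKUR_TRUE = np.array([
    0.65, 10.0, 8.5, 30.0, 59.0,   # alpha_ua
    0.65, 2.5, 82.0, 17.0,          # beta_ua
    3.0,                            # ua tau scale (K_Q10)
    30.3, 9.6,                      # ua steady state
    21.0, 185.0, 28.0,              # alpha_ui
    1.0, 158.0, 16.0,               # beta_ui
    3.0,                            # ui tau scale (K_Q10)
    99.45, 27.48,                   # ui steady state
    0.005, 0.05, 15.0, 13.0,        # voltage-dependent conductance
])


def _ikur_alpha_ua(p, V):
    V = np.asarray(V, dtype=float)
    with np.errstate(over="ignore"):
        return p[0] / (np.exp(-(V + p[1]) / p[2]) + np.exp(-(V - p[3]) / p[4]))


def _ikur_beta_ua(p, V):
    V = np.asarray(V, dtype=float)
    with np.errstate(over="ignore"):
        return p[5] / (p[6] + np.exp((V + p[7]) / p[8]))


def _ikur_alpha_ui(p, V):
    V = np.asarray(V, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (p[12] + np.exp(-(V - p[13]) / p[14]))


def _ikur_beta_ui(p, V):
    V = np.asarray(V, dtype=float)
    with np.errstate(over="ignore"):
        return p[15] * np.exp((V - p[16]) / p[17])


def _loewe_ikur_model() -> HHModel:
    def ua_inf(p, V):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) + p[10]) / p[11]))

    def ua_tau(p, V):
        return 1.0 / (p[9] * (_ikur_alpha_ua(p, V) + _ikur_beta_ua(p, V)))

    def ui_inf(p, V):
        return 1.0 / (1.0 + np.exp((np.asarray(V, float) - p[19]) / p[20]))

    def ui_tau(p, V):
        return 1.0 / (p[18] * (_ikur_alpha_ui(p, V) + _ikur_beta_ui(p, V)))

    def conductance(p, V):
        return p[21] + p[22] / (1.0 + np.exp(-(np.asarray(V, float) - p[23]) / p[24]))

    gates = [ExplicitGate(ua_inf, ua_tau, exponent=3), ExplicitGate(ui_inf, ui_tau)]
    rates = [
        RateExpression("general", func=lambda p, V: p[9] * _ikur_alpha_ua(p, V)),
        RateExpression("general", func=lambda p, V: p[9] * _ikur_beta_ua(p, V)),
        RateExpression("general", func=lambda p, V: p[18] * _ikur_alpha_ui(p, V)),
        RateExpression("general", func=lambda p, V: p[18] * _ikur_beta_ui(p, V)),
    ]
    return HHModel(gates=gates, conductance=conductance, E_rev=-85.0,
                   n_parameters=25, rates=rates, name="loewe_ikur")


LOEWE_IKUR_MULTIPLICATIVE = [0, 2, 4, 5, 6, 8, 9, 11, 12, 14, 15, 17, 18, 20, 21, 22, 24]
LOEWE_IKUR_ADDITIVE = [1, 3, 7, 10, 13, 16, 19, 23]


def _build_loewe_ikur():
    from chanbench.problems import BenchmarkProblem

    return BenchmarkProblem(
        name="loewe_ikur", model=_loewe_ikur_model(), protocols=loewe_protocols(),
        true_parameters=LOEWE_IKUR_TRUE, solver="hh_analytic",
        sampling=_loewe_sampling(25, LOEWE_IKUR_MULTIPLICATIVE, LOEWE_IKUR_ADDITIVE),
        log_indices=LOEWE_IKUR_MULTIPLICATIVE,
        cost_threshold=COST_THRESHOLDS["loewe_ikur"],
        n_run_default=N_RUN_DEFAULTS["loewe_ikur"],
        time_ratio=TIME_RATIOS["loewe_ikur"], data_seed=20204,
    )


# ---------------------------------------------------------------------------
# Moreno INa: 16-parameter five-state Markov model
# C3 <-> C2 <-> C1 <-> O <-> IF
# ---------------------------------------------------------------------------

MORENO_INA_TRUE = np.array([
    8.0, 0.03,      # C3->C2
    0.3, 0.06,      # C2->C3
    10.0, 0.035,    # C2->C1
    0.5, 0.055,     # C1->C2
    60.0, 0.08,     # C1->O   (fast activation; exceeds the standard rate cap)
    2.0, 0.10,      # O->C1   (fast deactivation; exceeds the standard rate cap)
    1.5,            # O->IF   (voltage-independent inactivation)
    1.0e-3, 0.05,   # IF->O   (recovery, voltage dependent)
    7.5,            # conductance
])

# The two activation-path rates are genuinely faster than 1000 ms^-1 at the
# true parameters; their upper rate bound is raised to 1e7 ms^-1 so that
# the truth stays accessible to every approach.
MORENO_RATE_UPPER_OVERRIDES = {4: 1e7, 5: 1e7}


def _moreno_ina_model() -> MarkovModel:
    C3, C2, C1, O, IF = range(5)
    transitions = [
        (C3, C2, RateExpression("pos_exp", A=0, b=1)),
        (C2, C3, RateExpression("neg_exp", A=2, b=3)),
        (C2, C1, RateExpression("pos_exp", A=4, b=5)),
        (C1, C2, RateExpression("neg_exp", A=6, b=7)),
        (C1, O, RateExpression("pos_exp", A=8, b=9)),
        (O, C1, RateExpression("neg_exp", A=10, b=11)),
        (O, IF, RateExpression("constant", A=12)),
        (IF, O, RateExpression("neg_exp", A=13, b=14)),
    ]
    return MarkovModel(n_states=5, transitions=transitions, open_index=O,
                       conductance=15, E_rev=41.0, n_parameters=16,
                       name="moreno_ina")


_MORENO_SPEC_CACHE = None


def moreno_summary_spec():
    """Protocol families for the four INa biomarkers.

    Returns a dict with keys 'activation', 'inactivation', 'recovery',
    'decay'; entries carry the prebuilt protocols and, where needed, index
    windows for the pulse-specific peaks.
    """
    global _MORENO_SPEC_CACHE
    if _MORENO_SPEC_CACHE is not None:
        return _MORENO_SPEC_CACHE

    hold = -120.0
    dt_fast = 0.05

    def window_times(t0, dur, dt):
        return t0 + np.arange(dt, dur + 1e-9, dt)

    activation = []
    for Vt in np.arange(-75.0, 20.0 + 1e-9, 5.0):
        times = window_times(500.0, 25.0, dt_fast)
        proto = VoltageProtocol(np.array([500.0, 25.0]), np.array([hold, Vt]), times)
        activation.append((Vt, proto))

    inactivation = []
    for Vpre in np.arange(-120.0, -40.0 + 1e-9, 5.0):
        times = window_times(1000.0, 25.0, dt_fast)
        proto = VoltageProtocol(np.array([500.0, 500.0, 25.0]),
                                np.array([hold, Vpre, -10.0]), times)
        inactivation.append((Vpre, proto))

    recovery = []
    for gap in (1.0, 3.0, 5.0, 10.0, 30.0, 100.0, 300.0, 1000.0):
        t1 = window_times(500.0, 25.0, dt_fast)
        t2 = window_times(600.0 + gap, 25.0, dt_fast)
        times = np.concatenate([t1, t2])
        proto = VoltageProtocol(
            np.array([500.0, 100.0, gap, 25.0]),
            np.array([hold, -10.0, hold, -10.0]), times)
        w1 = np.arange(t1.size)
        w2 = np.arange(t1.size, times.size)
        recovery.append((gap, proto, w1, w2))

    decay = []
    for Vt in np.arange(-30.0, 20.0 + 1e-9, 10.0):
        times = window_times(500.0, 50.0, 0.02)
        proto = VoltageProtocol(np.array([500.0, 50.0]), np.array([hold, Vt]), times)
        decay.append((Vt, proto, np.arange(times.size)))

    _MORENO_SPEC_CACHE = {
        "activation": activation,
        "inactivation": inactivation,
        "recovery": recovery,
        "decay": decay,
    }
    return _MORENO_SPEC_CACHE


def _build_moreno_ina():
    from chanbench.problems import BenchmarkProblem, SamplingSpec

    n = 16
    kinds = [("fraction", 0.25)] * n
    return BenchmarkProblem(
        name="moreno_ina", model=_moreno_ina_model(), protocols=[],
        true_parameters=MORENO_INA_TRUE, solver="markov_analytic",
        sampling=SamplingSpec(kinds), log_indices=list(range(n)),
        cost_threshold=COST_THRESHOLDS["moreno_ina"],
        n_run_default=N_RUN_DEFAULTS["moreno_ina"],
        time_ratio=TIME_RATIOS["moreno_ina"], data_seed=20205,
        rate_upper_overrides=MORENO_RATE_UPPER_OVERRIDES,
        summary_spec=moreno_summary_spec(),
    )


# ---------------------------------------------------------------------------
# Fixture: 3-parameter single-gate toy problem
# ---------------------------------------------------------------------------

FIXTURE_TRUE = np.array([0.02, 0.05, 0.5])


def _fixture_model() -> HHModel:
    alpha = RateExpression("pos_exp", A=0, b=1)
    beta = RateExpression("neg_exp", A=0.03, b=0.05)  # fixed closing rate
    gate = RateGate(alpha, beta)
    return HHModel(gates=[gate], conductance=2, E_rev=-85.0, n_parameters=3,
                   rates=[alpha, beta], name="fixture_hh")


def _build_fixture():
    from chanbench.problems import BenchmarkProblem, SamplingSpec

    proto = VoltageProtocol.from_steps(
        [(500.0, -80.0), (500.0, 20.0), (500.0, -40.0)], dt=2.0)
    kinds = [("log_factor", 0.1, 10.0), ("fraction", 0.5), ("log_factor", 0.1, 10.0)]
    return BenchmarkProblem(
        name="fixture_hh", model=_fixture_model(), protocols=[proto],
        true_parameters=FIXTURE_TRUE, solver="hh_analytic",
        sampling=SamplingSpec(kinds), log_indices=[0, 2],
        cost_threshold=COST_THRESHOLDS["fixture_hh"],
        n_run_default=N_RUN_DEFAULTS["fixture_hh"],
        time_ratio=TIME_RATIOS["fixture_hh"], data_seed=20206,
    )


BUILDERS = {
    "staircase_hh": _build_staircase_hh,
    "staircase_mm": _build_staircase_mm,
    "loewe_ikr": _build_loewe_ikr,
    "loewe_ikur": _build_loewe_ikur,
    "moreno_ina": _build_moreno_ina,
    "fixture_hh": _build_fixture,
}
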