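"""Monodomain solver: Laplacian/boundary behavior, CV measurement,
decoupling, and the tissue stimulus machinery."""

import numpy as np
import pytest
from numba import njit

from atrialbench.cell_models import IonicModel, _run_cell, make_stepper
from atrialbench.monodomain_solver import (
    ConductionBlock,
    VmMovie,
    activation_from_movie,
    find_tissue_threshold,
    measure_cv,
    run_strand,
)
from atrialbench.synthetic_fixtures import MOCK_DIFFUSIVITY


@njit
def _null_core(s, p, istim, d, yinf, tau):
    d[0] = istim
    d[1] = 0.0


def _null_model() -> IonicModel:
    """Membrane with no ionic currents: V changes only by diffusion and
    stimulus."""
    step = make_stepper(_null_core, 2, [1])
    return IonicModel(
        name="null", variant="control",
        state_names=("V", "g"), state_units=("mV", "1"),
        param_names=(), params=np.empty(0),
        initial_state=np.array([-80.0, 0.5]),
        gating_index=np.array([], dtype=np.int64),
        stiff_index=np.array([], dtype=np.int64),
        current_names=("I_null",), cai_index=-1, cm=1.0, caf_scaling={},
        core=_null_core, step=step,
        currents_fn=njit(lambda s, p, out: None),
    )


def test_uniform_resting_grid_stays_uniform(mock_cell_basic):
    """Laplacian of a constant field is zero: no stimulus, no change."""
    mock = mock_cell_basic
    states = np.tile(mock.initial_state, (50, 1))
    run_strand(mock, states, 0.2, 500, dt=0.02)
    assert np.ptp(states[:, 0]) == 0.0


def test_no_flux_conserves_mean_voltage():
    """With I_ion = 0 the spatial mean of V is conserved to round-off under
    pure diffusion (1D)."""
    model = _null_model()
    rng = np.random.default_rng(3)
    states = np.zeros((80, 2))
    states[:, 0] = rng.uniform(-90.0, 20.0, size=80)
    mean0 = states[:, 0].mean()
    run_strand(model, states, 0.3, 2000, dt=0.01, dx=0.1)
    assert states[:, 0].mean() == pytest.approx(mean0, abs=1e-9)
    assert np.ptp(states[:, 0]) < np.ptp(rng.uniform(size=2)) + 60.0  # relaxed


def test_zero_diffusivity_decouples_voxels_bitwise(mock_cell_basic):
    """With D = 0 a strand voxel reproduces the single-cell integration
    exactly (same update sequence, zero coupling term)."""
    mock = mock_cell_basic
    nx = 8
    states = np.tile(mock.initial_state, (nx, 1))
    run_strand(
        mock, states, 0.0, 5000, dt=0.02,
        stim_amp=5.0, stim_period=6000, stim_dur=100, n_stims=1,
    )
    s_single = mock.initial_state.copy()
    _run_cell(
        mock, s_single, 0.02, 5000, stim_amp=5.0, stim_period=6000,
        stim_dur=100, n_stims=1,
    )
    np.testing.assert_array_equal(states[0], s_single)  # stimulated voxel
    np.testing.assert_array_equal(states[-1], mock.initial_state)  # untouched


def test_measure_cv_on_linear_activation_map():
    """t(x) = x / 0.75 (ms per mm) gives exactly 750 mm/s."""
    nx, dx = 200, 0.1
    act = np.arange(nx) * dx / 0.75
    assert measure_cv(act, dx) == pytest.approx(750.0, rel=1e-12)


def test_measure_cv_raises_on_block():
    act = np.arange(200) * 0.1 / 0.75
    act[150:] = -1.0  # distal half never activates
    with pytest.raises(ConductionBlock, match="block"):
        measure_cv(act, 0.1)


def test_cv_independent_of_strand_length(mock_cell_basic):
    """Planar-wave CV on a mock strand differs < 1% between 20 and 40 mm
    strands (boundary margins aside)."""
    mock = mock_cell_basic
    base = np.tile(mock.initial_state, (200, 1))
    amp = 1.2 * find_tissue_threshold(mock, base, MOCK_DIFFUSIVITY, dt=0.02)

    def cv_for(nx):
        states = np.tile(mock.initial_state, (nx, 1))
        res = run_strand(
            mock, states, MOCK_DIFFUSIVITY, 15000, dt=0.02,
            stim_amp=amp, stim_period=20000, stim_dur=100, n_stims=1,
        )
        return measure_cv(res.act_t, 0.1, nx // 4, 3 * nx // 4)

    assert cv_for(200) == pytest.approx(cv_for(400), rel=0.01)


def test_activation_from_movie_matches_kernel_activation(mock_cell_basic):
    """Offline movie-based activation times agree with the in-kernel
    max-dV/dt tracker within one sample interval."""
    mock = mock_cell_basic
    states = np.tile(mock.initial_state, (100, 1))
    amp = 1.2 * find_tissue_threshold(mock, states, MOCK_DIFFUSIVITY, dt=0.02)
    res = run_strand(
        mock, states, MOCK_DIFFUSIVITY, 10000, dt=0.02,
        stim_amp=amp, stim_period=20000, stim_dur=100, n_stims=1,
        probe_idx=np.arange(100), sample_every=5,
    )
    assert res.act_vmax[90] > 0  # the wave really crossed the strand
    movie = VmMovie(data=res.probe_v, dt=res.probe_dt, dx=0.1)
    act = activation_from_movie(movie)
    sel = slice(10, 90)
    assert np.max(np.abs(act[sel] - res.act_t[sel])) < 2 * res.probe_dt


def test_cfl_violation_warns(mock_cell_basic):
    mock = mock_cell_basic
    states = np.tile(mock.initial_state, (10, 1))
    with pytest.warns(UserWarning, match="stability"):
        run_strand(mock, states, 5.0, 1, dt=0.02, dx=0.1)
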