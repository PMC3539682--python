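"""Synthetic inputs with known ground truth.

These fixtures let every protocol and analysis stage be exercised without
any ionic model: a mock excitable cell with dial-in AP characteristics, a
traveling plane-wave V_m movie with analytic activation times, and a
rigidly rotating ideal vortex phase field.  Everything here is fully
deterministic.

The mock cell is a two-variable excitable system in the style of
Mitchell–Schaeffer: a cubic-nonlinearity voltage variable and one slow
recovery gate h with voltage-dependent open/close time constants, mapped
onto the requested resting potential and AP amplitude.  Its action
potential duration is set by the gate's closing time constant and its
absolute refractory period by the reopening time constant; both knobs are
calibrated at construction by simulate-and-adjust through the same
protocol code paths (pacing + feature extraction for APD, the strand ERP
measurement for the refractory period) that the ionic models use.  It
conforms to the ionic-model plugin contract, so every protocol module
accepts it.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .cell_models import (
    IonicModel,
    ModelError,
    make_stepper,
    register_model,
)
from .cell_models._engine import FASTMATH
from .monodomain_solver import VmMovie

__all__ = [
    "make_mock_cell",
    "make_plane_wave_movie",
    "make_vortex_phase_movie",
    "MOCK_DIFFUSIVITY",
]

#: diffusivity used for mock-cell strands (mm^2/ms); not tuned — fixture
#: conduction speed is not a calibrated quantity.
MOCK_DIFFUSIVITY = 0.1

_STATE_NAMES = ("V", "h")
_STATE_UNITS = ("mV", "1")
_PARAM_NAMES = (
    "rmp", "amplitude", "tau_in", "tau_out", "tau_open", "tau_close", "vgate",
)
_GATES = np.array([1], dtype=np.int64)


@njit(fastmath=FASTMATH)
def _mock_core(s, p, istim, d, yinf, tau):
    rmp, amp, tau_in, tau_out, tau_open, tau_close, vgate = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    )
    u = (s[0] - rmp) / amp
    h = s[1]
    d[0] = amp * (h * u * u * (1.0 - u) / tau_in - u / tau_out) + istim
    if u < vgate:
        yinf[1] = 1.0
        tau[1] = tau_open
    else:
        yinf[1] = 0.0
        tau[1] = tau_close
    d[1] = (yinf[1] - h) / tau[1]


@njit(fastmath=FASTMATH)
def _mock_currents(s, p, out):
    rmp, amp, tau_in, tau_out = p[0], p[1], p[2], p[3]
    u = (s[0] - rmp) / amp
    out[0] = -amp * s[1] * u * u * (1.0 - u) / tau_in  # inward
    out[1] = amp * u / tau_out  # outward


_mock_step = make_stepper(_mock_core, 2, _GATES)


def _build_mock(params: np.ndarray, name: str) -> IonicModel:
    return IonicModel(
        name=name,
        variant="control",
        state_names=_STATE_NAMES,
        state_units=_STATE_UNITS,
        param_names=_PARAM_NAMES,
        params=params,
        initial_state=np.array([params[0], 1.0]),
        gating_index=_GATES.copy(),
        stiff_index=np.empty(0, dtype=np.int64),
        current_names=("I_in", "I_out"),
        cai_index=-1,
        cm=1.0,
        caf_scaling={},
        core=_mock_core,
        step=_mock_step,
        currents_fn=_mock_currents,
    )


def _measure_apd(model: IonicModel, bcl_s: float, dt: float) -> float:
    from .single_cell_protocols import extract_ap_features, pace

    trace = pace(model, bcl=bcl_s, duration=3 * bcl_s, dt=dt, dt_sample=0.1)
    return extract_ap_features(trace, -1).apd90


def _measure_erp_strand(model: IonicModel, bcl_s: float, dt: float) -> float:
    from .restitution_1d import measure_erp, run_strand_protocol

    proto = run_strand_protocol(
        model, bcl_s, diffusivity=MOCK_DIFFUSIVITY, dt=dt
    )
    return measure_erp(model, bcl_s, proto, dt=dt)


def make_mock_cell(
    rmp: float = -80.0,
    amplitude: float = 110.0,
    apd: float = 150.0,
    refractory: float | None = None,
    *,
    dt: float = 0.02,
    apd_tol: float = 2.0,
    erp_tol: float = 1.5,
    register: bool = True,
) -> IonicModel:
    """Mock excitable cell with requested RMP (mV), AP amplitude (mV),
    APD90 (ms) and, optionally, absolute refractory period (ms).

    Calibration is simulate-and-adjust: the gate closing time constant is
    fitted so paced APD90 matches ``apd``; if ``refractory`` is given, the
    reopening time constant is fitted so the strand ERP matches it.
    Raises :class:`ModelError` (reporting the achieved values) for
    unattainable combinations, e.g. ``amplitude <= 0`` (inexcitable) or a
    refractory period shorter than the AP itself supports.
    """
    if apd <= 0:
        raise ModelError("apd must be > 0")
    if amplitude <= 0:
        raise ModelError("inexcitable: amplitude must be > 0")
    if refractory is not None and refractory < 0.5 * apd:
        raise ModelError("refractory must be >= apd/2")
    tau_in, tau_out, vgate = 0.3, 6.0, 0.13
    h_min = 4.0 * tau_in / tau_out
    tau_close = apd / np.log(1.0 / h_min)
    tau_open = max(apd, refractory if refractory else apd) / 1.5
    amp_cal = amplitude  # V-scale parameter; peak u stays slightly below 1
    bcl_s = max(1.0, 3.0 * max(apd, refractory or apd) / 1000.0)

    def params() -> np.ndarray:
        return np.array(
            [rmp, amp_cal, tau_in, tau_out, tau_open, tau_close, vgate]
        )

    # APD: measured APD90 scales (near-)linearly with tau_close; the
    # amplitude scale is corrected alongside (it does not affect APD)
    from .single_cell_protocols import extract_ap_features, pace

    measured_apd = math_nan = float("nan")
    for _ in range(6):
        trace = pace(
            _build_mock(params(), "mock"), bcl=bcl_s, duration=3 * bcl_s,
            dt=dt, dt_sample=0.1,
        )
        f = extract_ap_features(trace, -1)
        measured_apd = f.apd90
        amp_cal *= amplitude / f.amplitude
        if abs(measured_apd - apd) <= 0.5 * apd_tol:
            break
        tau_close *= apd / measured_apd
    model = _build_mock(params(), "mock")
    measured_apd = _measure_apd(model, bcl_s, dt)
    if abs(measured_apd - apd) > apd_tol:
        raise ModelError(
            f"mock-cell APD calibration failed: requested {apd} ms, "
            f"achieved {measured_apd:.1f} ms"
        )

    if refractory is not None:
        # ERP ~ APD + recovery interval growing with tau_open; secant on
        # the last two (tau_open, ERP) evaluations of the strand protocol
        prev = None
        erp = _measure_erp_strand(model, bcl_s, dt)
        for _ in range(12):
            if abs(erp - refractory) <= max(0.5 * erp_tol, 0.5):
                break
            if prev is not None and abs(erp - prev[1]) > 1e-9:
                slope = (erp - prev[1]) / (tau_open - prev[0])
                new_tau = (
                    tau_open + (refractory - erp) / slope
                    if slope > 1e-6
                    else tau_open * refractory / erp
                )
            else:
                new_tau = tau_open * refractory / erp
            prev = (tau_open, erp)
            tau_open = float(np.clip(new_tau, 1.0, 5000.0))
            model = _build_mock(params(), "mock")
            erp = _measure_erp_strand(model, bcl_s, dt)
        if abs(erp - refractory) > erp_tol:
            raise ModelError(
                f"mock-cell ERP calibration failed: requested {refractory} "
                f"ms, achieved {erp:.1f} ms (APD {measured_apd:.1f} ms)"
            )

    name = f"mock-{rmp:g}-{amplitude:g}-{apd:g}-{refractory or 0:g}"
    model = _build_mock(params(), name)
    if register:
        register_model(name, lambda m=model: m)
    return model


def _default_waveform(apd: float):
    """Stereotyped AP waveform g(t) in [0, 1]: sigmoid upstroke (maximum
    slope at t = 0) with smooth repolarization ending by ~apd."""

    def g(t):
        up = 1.0 / (1.0 + np.exp(-t / 0.5))
        rep = 1.0 / (1.0 + np.exp((t - apd) / (0.05 * apd)))
        return up * rep

    return g


def make_plane_wave_movie(
    speed: float,
    *,
    direction=(1.0, 0.0),
    shape=(1, 200),
    dx: float = 0.1,
    dt_sample: float = 0.1,
    duration: float | None = None,
    rmp: float = -80.0,
    amplitude: float = 100.0,
    apd: float = 120.0,
    t_start: float = 5.0,
) -> VmMovie:
    """Planar wave of known speed (mm/s) crossing a 1D strand or 2D patch.

    The activation time of voxel center r is analytically
    ``t_start + dot(r - r0, direction) / speed`` with the wavefront entering
    at the most upstream voxel; the waveform's maximum slope marks
    activation, so activation-time *differences* recover the speed exactly.
    ``shape`` is (ny, nx); use ny=1 for a strand.  ``direction`` need not
    be axis-aligned.
    """
    if speed <= 0:
        raise ValueError("speed must be > 0")
    ny, nx = shape
    v_mm_ms = speed / 1e3
    dvec = np.asarray(direction, dtype=float)
    dvec = dvec / np.hypot(*dvec)
    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dx
    gx, gy = np.meshgrid(xs, ys)
    proj = gx * dvec[0] + gy * dvec[1]
    proj = proj - proj.min()
    t_act = t_start + proj / v_mm_ms
    if duration is None:
        duration = float(t_act.max() + apd * 1.8)
    t = np.arange(0.0, duration, dt_sample)
    g = _default_waveform(apd)
    data = rmp + amplitude * g(t[:, None, None] - t_act[None, :, :])
    if ny == 1:
        data = data[:, 0, :]
    return VmMovie(data=data, dt=dt_sample, dx=dx)


def make_vortex_phase_movie(
    center=(5.0, 5.0),
    chirality: int = 1,
    frequency: float = 5.0,
    *,
    size_mm: float = 10.0,
    dx: float = 0.1,
    dt_sample: float = 5.0,
    duration: float = 1000.0,
):
    """Rigidly rotating ideal vortex phase field.

    theta(x, y, t) = chirality * atan2(y - cy, x - cx) - 2*pi*f*t, wrapped
    to (-pi, pi].  Returns ``(phases, dt_sample, dx)`` with phases of shape
    (nt, ny, nx); the singularity sits at ``center`` (mm) with topological
    charge ``chirality``, and the local signal cos(theta) at any probe
    voxel oscillates at exactly ``frequency`` Hz.
    """
    if chirality not in (-1, 1):
        raise ValueError("chirality must be +-1")
    n = int(round(size_mm / dx))
    xs = (np.arange(n) + 0.5) * dx
    gx, gy = np.meshgrid(xs, xs)
    base = chirality * np.arctan2(gy - center[1], gx - center[0])
    t = np.arange(0.0, duration, dt_sample)
    om = 2.0 * np.pi * frequency / 1e3  # rad/ms
    ph = base[None, :, :] - om * t[:, None, None]
    ph = (ph + np.pi) % (2.0 * np.pi) - np.pi
    return ph, dt_sample, dx
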