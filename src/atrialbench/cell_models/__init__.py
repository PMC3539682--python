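"""Ionic cell models: plugin contract, registry, clamp and threshold tools.

Built-in models: ``courtemanche``, ``nygren``, ``maleckar`` (append
``-caf`` for the chronic-AF remodeled variant).  Further models (e.g. the
Koivumäki or Grandi formulations) can be added through
:func:`register_model` without touching the protocol modules; the generic
stepper factory supports per-state RK4 sub-integration for stiff calcium
states as those models require.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from ._base import (
    CAF_FACTORS,
    IonicModel,
    ModelError,
    apply_caf_remodeling,
    get_model,
    list_models,
    register_model,
)
from ._engine import make_stepper
from . import courtemanche as _courtemanche
from . import nygren_family as _nygren_family

register_model("courtemanche", _courtemanche.build)
register_model("nygren", _nygren_family.build_nygren)
register_model("maleckar", _nygren_family.build_maleckar)

__all__ = [
    "CAF_FACTORS",
    "IonicModel",
    "ModelError",
    "apply_caf_remodeling",
    "get_model",
    "list_models",
    "register_model",
    "make_stepper",
    "run_free",
    "voltage_clamp",
    "paced_current_extrema",
    "find_threshold",
]

DT_DEFAULT = 0.01  # ms


def _run_cell(
    model: IonicModel,
    state: np.ndarray,
    dt: float,
    n_steps: int,
    *,
    stim_amp: float = 0.0,
    stim_first: int = 0,
    stim_period: int = 0,
    stim_dur: int = 0,
    n_stims: int = 0,
    sample_every: int = 0,
    vhold: float = math.nan,
    track_extrema: bool = False,
):
    """Low-level single-cell driver; mutates ``state`` in place."""
    kernel = model.kernel("cell")
    n_samples = n_steps // sample_every + 1 if sample_every > 0 else 0
    v = np.empty(n_samples)
    cai = np.full(n_samples, np.nan)
    n_cur = len(model.current_names)
    cur_min = np.full(n_cur, np.inf)
    cur_max = np.full(n_cur, -np.inf)
    ns = kernel(
        state,
        model.params,
        dt,
        n_steps,
        stim_amp,
        stim_first,
        stim_period,
        stim_dur,
        n_stims,
        sample_every,
        v,
        cai,
        model.cai_index,
        vhold,
        track_extrema,
        cur_min,
        cur_max,
    )
    if ns < 0:
        raise ModelError(
            f"{model.key}: V_m became NaN at t = {-ns * dt:.3f} ms"
        )
    return v[:ns], cai[:ns], cur_min, cur_max


def run_free(
    model: IonicModel,
    duration: float,
    state=None,
    dt: float = DT_DEFAULT,
) -> np.ndarray:
    """Relax the model without stimulation for ``duration`` ms; returns the
    final state (input state is not modified)."""
    s = np.array(model.initial_state if state is None else state, dtype=float)
    _run_cell(model, s, dt, int(round(duration / dt)))
    return s


def voltage_clamp(
    model: IonicModel,
    v_hold: float = -75.0,
    duration: float = 50_000.0,
    state=None,
    dt: float = DT_DEFAULT,
    drift_tol: float = 1e-7,
) -> dict[str, float]:
    """Hold V_m at ``v_hold`` mV for ``duration`` ms (all other states free)
    and return the instantaneous currents at the end of the clamp.

    Used to compute the normalization divisor |I_K1(-75 mV, 50 s)| with
    which paced current extrema are made comparable across models.  Warns
    (but still returns) if concentrations are still drifting at the end.
    """
    s = np.array(model.initial_state if state is None else state, dtype=float)
    s[0] = v_hold
    _run_cell(model, s, dt, int(round(duration / dt)), vhold=v_hold)
    d, _, _ = model.derivatives(s, t=duration)
    conc = [
        i
        for i, u in enumerate(model.state_units)
        if u == "mM" and i != 0
    ]
    drift = float(np.max(np.abs(d[conc]))) if conc else 0.0
    if drift > drift_tol:
        warnings.warn(
            f"{model.key}: concentrations still drifting at end of clamp "
            f"(max |d[X]/dt| = {drift:.2e} mM/ms)",
            stacklevel=2,
        )
    return model.current_snapshot(s)


def ik1_divisor(model: IonicModel, **kwargs) -> float:
    """|I_K1| after the 50 s, -75 mV clamp of the *control* variant."""
    base = get_model(model.name) if model.variant != "control" else model
    return abs(voltage_clamp(base, **kwargs)["I_K1"])


def paced_current_extrema(
    model: IonicModel,
    bcl: float = 1.0,
    duration: float = 50.0,
    stim_amp: float | None = None,
    dt: float = DT_DEFAULT,
    normalize: bool = True,
) -> dict[str, tuple[float, float]]:
    """(min, max) of each sarcolemmal current over the final paced beat.

    Paces ``duration`` s at basic cycle length ``bcl`` s with a 2 ms pulse
    at twice diastolic threshold, tracking current extrema at every
    integration step of the terminal beat.  With ``normalize`` the values
    are divided by the control variant's clamped-I_K1 divisor, the scale on
    which cross-model current tables are reported.
    """
    amp = 2.0 * find_threshold(model, dt=dt) if stim_amp is None else stim_amp
    period = int(round(bcl * 1000.0 / dt))
    n_beats = int(round(duration / bcl))
    dur = int(round(2.0 / dt))
    s = np.array(model.initial_state, dtype=float)
    _run_cell(
        model, s, dt, (n_beats - 1) * period,
        stim_amp=amp, stim_period=period, stim_dur=dur, n_stims=n_beats - 1,
    )
    _, _, cmin, cmax = _run_cell(
        model, s, dt, period,
        stim_amp=amp, stim_period=period, stim_dur=dur, n_stims=1,
        track_extrema=True,
    )
    div = ik1_divisor(model, dt=dt) if normalize else 1.0
    return {
        name: (cmin[i] / div, cmax[i] / div)
        for i, name in enumerate(model.current_names)
    }


def find_threshold(
    model: IonicModel,
    pulse_duration: float = 2.0,
    state=None,
    dt: float = DT_DEFAULT,
    window: float = 50.0,
    rtol: float = 0.01,
    initial_guess: float = 4.0,
) -> float:
    """Diastolic stimulus threshold (pA/pF) for a rectangular pulse.

    Minimal amplitude for which the pulse elicits an AP (peak V_m > 0 mV
    within ``window`` ms), found by bracketing + bisection to ``rtol``
    relative precision from the given reference state (default: the model's
    resting initial state, i.e. the state from which a protocol delivers
    its first stimulus).
    """
    s0 = np.array(model.initial_state if state is None else state, dtype=float)
    n_steps = int(round(window / dt))
    dur = int(round(pulse_duration / dt))

    def elicits(amp: float) -> bool:
        s = s0.copy()
        v, _, _, _ = _run_cell(
            model, s, dt, n_steps,
            stim_amp=amp, stim_period=n_steps + 1, stim_dur=dur, n_stims=1,
            sample_every=max(1, int(round(0.1 / dt))),
        )
        return bool(np.max(v) > 0.0)

    hi = float(initial_guess)
    ceiling = initial_guess * 100.0
    while not elicits(hi):
        hi *= 2.0
        if hi > ceiling:
            raise ModelError(
                f"{model.key}: inexcitable (no AP at stimulus {hi:.1f} pA/pF)"
            )
    lo = 0.0
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if elicits(mid):
            hi = mid
        else:
            lo = mid
    return hi
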