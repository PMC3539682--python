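"""Explicit finite-difference monodomain solver for 1D strands and 2D patches.

The transmembrane voltage obeys the monodomain reaction–diffusion equation

    dV/dt = D * lap(V) - I_ion / C_m + I_stim

on a lattice of cubic voxels (default dx = 0.1 mm) with no-flux boundaries,
a 3-point (1D) or 5-point (2D) Laplacian and the same explicit cell update
(Rush–Larsen + forward Euler) as the single-cell protocols.  ``D`` is the
effective diffusivity in mm^2/ms; the intracellular conductivity, the
surface-to-volume ratio and C_m enter only through this one constant, which
is tuned per model so that a planar wave conducts at ~750 mm/s at a basic
cycle length of 1 s in the control variant — so their individual values do
not affect any benchmarked quantity.  The chronic-AF variants reuse the
control-tuned D scaled by 0.70 (30% conductivity reduction from gap
junctional remodeling).

Activation time of a voxel is the time of its maximum dV/dt during the
upstroke; conduction velocity divides the distance between the centers of
the two strand halves by the difference of their activation times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cell_models import DT_DEFAULT, IonicModel, ModelError, find_threshold

__all__ = [
    "DX_DEFAULT",
    "CAF_CONDUCTIVITY_FACTOR",
    "VmMovie",
    "StrandResult",
    "ConductionBlock",
    "run_strand",
    "run_patch",
    "measure_cv",
    "activation_from_movie",
    "find_tissue_threshold",
    "tune_conductivity",
    "strand_cv",
    "prepace_state",
]

DX_DEFAULT = 0.1  # mm, cubic voxels
CAF_CONDUCTIVITY_FACTOR = 0.70  # 30% intracellular conductivity reduction
STRAND_LENGTH_MM = 20.0
STIM_VOXELS = 2  # stimulus injected into the first 2 voxel columns
TISSUE_STIM_SCALE = 1.2  # 20% above tissue threshold


class ConductionBlock(RuntimeError):
    """A measurement site never activated."""


@dataclass
class VmMovie:
    """Sampled V_m frames on a 1D or 2D lattice."""

    data: np.ndarray  # (nt, nx) or (nt, ny, nx)
    dt: float  # ms between frames
    dx: float  # mm
    t0: float = 0.0

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.data.shape[0])


@dataclass
class StrandResult:
    """Outcome of a 1D strand run."""

    act_t: np.ndarray  # ms, per-voxel activation time (max dV/dt) in window
    act_dvdt: np.ndarray  # V/s
    act_vmax: np.ndarray  # mV, per-voxel max V in window
    probe_idx: np.ndarray
    probe_v: np.ndarray  # (nt, n_probes)
    probe_dt: float
    dt: float
    dx: float
    states: np.ndarray  # final per-voxel states (nx, n_state)


def _check_cfl(diff: float, dt: float, dx: float, dim: int) -> None:
    r = diff * dt / (dx * dx)
    if 2 * dim * r > 1.0:
        warnings.warn(
            f"diffusion number {r:.3f} violates the explicit stability bound "
            f"dt <= dx^2/({2 * dim}*D); expect oscillations",
            stacklevel=3,
        )


def run_strand(
    model: IonicModel,
    states: np.ndarray,
    diffusivity: float,
    n_steps: int,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    stim_amp: float = 0.0,
    stim_first: int = 0,
    stim_period: int = 0,
    stim_dur: int = 0,
    n_stims: int = 0,
    act_from_step: int = 0,
    probe_idx=(),
    sample_every: int = 0,
) -> StrandResult:
    """Advance a strand in place; see :class:`StrandResult`.

    ``states`` is the (nx, n_state) per-voxel state array (mutated).  The
    stimulus is a transmembrane current in the first ``STIM_VOXELS`` voxels
    with the step-based schedule of the cell kernels.
    """
    _check_cfl(diffusivity, dt, dx, 1)
    nx = states.shape[0]
    kernel = model.kernel("strand")
    act_k = np.full(nx, -1, dtype=np.int64)
    act_dvdt = np.zeros(nx)
    act_prev = np.zeros(nx)
    act_next = np.zeros(nx)
    act_vmax = np.full(nx, -1e30)
    probe_idx = np.asarray(probe_idx, dtype=np.int64)
    n_frames = n_steps // sample_every + 1 if sample_every > 0 else 0
    probe_v = np.empty((n_frames, probe_idx.size))
    status = kernel(
        states,
        model.params,
        dt,
        n_steps,
        diffusivity * dt / (dx * dx),
        stim_amp,
        0,
        STIM_VOXELS,
        stim_first,
        stim_period,
        stim_dur,
        n_stims,
        act_from_step,
        act_k,
        act_dvdt,
        act_prev,
        act_next,
        act_vmax,
        sample_every,
        probe_idx,
        probe_v,
    )
    if status < 0:
        raise ModelError(
            f"{model.key}: NaN in strand at t = {-status * dt:.3f} ms"
        )
    # activation time: midpoint of the max-slope interval, refined to
    # sub-step precision by the parabola through the neighbouring slopes
    act_t = np.full(nx, -1.0)
    active = act_k >= 0
    den = act_prev - 2.0 * act_dvdt + act_next
    off = np.zeros(nx)
    interior = active & (act_k > act_from_step) & (den != 0.0)
    off[interior] = 0.5 * (act_prev[interior] - act_next[interior]) / den[interior]
    off = np.clip(off, -0.5, 0.5)
    act_t[active] = (act_k[active] + 0.5 + off[active]) * dt
    return StrandResult(
        act_t=act_t,
        act_dvdt=act_dvdt,
        act_vmax=act_vmax,
        probe_idx=probe_idx,
        probe_v=probe_v[:status] if sample_every > 0 else probe_v,
        probe_dt=sample_every * dt if sample_every > 0 else float("nan"),
        dt=dt,
        dx=dx,
        states=states,
    )


def run_patch(
    model: IonicModel,
    states: np.ndarray,
    diffusivity: float,
    n_steps: int,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    s1_amp: float = 0.0,
    s1_first: int = 0,
    s1_period: int = 0,
    s1_dur: int = 0,
    n_s1: int = 0,
    s2_amp: float = 0.0,
    s2_first: int = 0,
    s2_dur: int = 0,
    s2_rows: int = 0,
    sample_every: int = 0,
) -> VmMovie | None:
    """Advance a 2D patch in place; S1 planar stimuli on the left edge,
    one cross-field S2 over the lower ``s2_rows`` rows.  Returns the V_m
    movie when ``sample_every`` > 0."""
    _check_cfl(diffusivity, dt, dx, 2)
    ny, nx = states.shape[:2]
    kernel = model.kernel("patch")
    n_frames = n_steps // sample_every + 1 if sample_every > 0 else 0
    movie = np.empty((n_frames, ny, nx), dtype=np.float32)
    status = kernel(
        states,
        model.params,
        dt,
        n_steps,
        diffusivity * dt / (dx * dx),
        s1_amp,
        STIM_VOXELS,
        s1_first,
        s1_period,
        s1_dur,
        n_s1,
        s2_amp,
        s2_first,
        s2_dur,
        s2_rows,
        sample_every,
        movie,
    )
    if status < 0:
        raise ModelError(
            f"{model.key}: NaN in patch at t = {-status * dt:.3f} ms"
        )
    if sample_every > 0:
        return VmMovie(data=movie[:status], dt=sample_every * dt, dx=dx)
    return None


def measure_cv(
    act_t: np.ndarray,
    dx: float = DX_DEFAULT,
    site1: int | None = None,
    site2: int | None = None,
) -> float:
    """Conduction velocity (mm/s) from a strand activation-time map.

    Divides the distance between the centers of the first and second strand
    halves (overridable via ``site1``/``site2``) by the activation-time
    difference.  Raises :class:`ConductionBlock` if either site never
    activated (activation time < 0).
    """
    act_t = np.asarray(act_t, dtype=float)
    nx = act_t.size
    i1 = nx // 4 if site1 is None else site1
    i2 = 3 * nx // 4 if site2 is None else site2
    for i in (i1, i2):
        if act_t[i] < 0:
            raise ConductionBlock(f"conduction block: voxel {i} never activated")
    dt_act = act_t[i2] - act_t[i1]
    if dt_act <= 0:
        raise ConductionBlock("conduction block: non-positive activation delay")
    return abs(i2 - i1) * dx / dt_act * 1e3  # mm/ms -> mm/s


def activation_from_movie(movie: VmMovie) -> np.ndarray:
    """Per-voxel activation times (ms) from a sampled V_m movie.

    Activation is the frame interval of maximum temporal dV/dt, refined by
    parabolic interpolation of the three dV/dt samples around the peak
    (exact for a symmetric upstroke, sub-frame accurate otherwise).  Voxels
    whose V_m never exceeds -20 mV are marked -1 (not activated).
    """
    v = movie.data.astype(np.float64)
    nt = v.shape[0]
    flat = v.reshape(nt, -1)
    dv = np.diff(flat, axis=0)
    k = np.argmax(dv, axis=0)
    out = np.empty(flat.shape[1])
    for i in range(flat.shape[1]):
        ki = k[i]
        off = 0.0
        if 0 < ki < dv.shape[0] - 1:
            a, b, c = dv[ki - 1, i], dv[ki, i], dv[ki + 1, i]
            den = a - 2 * b + c
            if den != 0:
                off = 0.5 * (a - c) / den
        out[i] = movie.t0 + (ki + 0.5 + off) * movie.dt
        if np.max(flat[:, i]) < -20.0:
            out[i] = -1.0
    return out.reshape(v.shape[1:])


def find_tissue_threshold(
    model: IonicModel,
    states0: np.ndarray,
    diffusivity: float,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    pulse_duration: float = 2.0,
    window: float = 60.0,
    rtol: float = 0.01,
    initial_guess: float = 10.0,
) -> float:
    """Stimulus threshold (pA/pF) for the strand's edge stimulus, by
    bracketing + bisection (AP detected 2 mm into the strand)."""
    n_steps = int(round(window / dt))
    dur = int(round(pulse_duration / dt))
    detect = max(int(round(2.0 / dx)), STIM_VOXELS + 1)

    def elicits(amp: float) -> bool:
        st = states0.copy()
        res = run_strand(
            model, st, diffusivity, n_steps, dt=dt, dx=dx,
            stim_amp=amp, stim_period=n_steps + 1, stim_dur=dur, n_stims=1,
        )
        return bool(res.act_vmax[detect] > 0.0)

    hi = float(initial_guess)
    while not elicits(hi):
        hi *= 2.0
        if hi > initial_guess * 200.0:
            raise ModelError(f"{model.key}: strand inexcitable")
    lo = 0.0
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if elicits(mid):
            hi = mid
        else:
            lo = mid
    return hi


_PREPACE_CACHE: dict = {}


def prepace_state(
    model: IonicModel,
    bcl: float,
    n_beats: int = 50,
    dt: float = DT_DEFAULT,
) -> np.ndarray:
    """Single-cell state after ``n_beats`` paced beats at ``bcl`` (s), used
    to seed every tissue voxel (memoized per model/BCL/dt)."""
    key = (model.key, round(bcl, 6), n_beats, dt)
    if key not in _PREPACE_CACHE:
        from .single_cell_protocols import pace

        _, s = pace(
            model, bcl=bcl, duration=n_beats * bcl, dt=dt, dt_sample=1.0,
            return_state=True,
        )
        _PREPACE_CACHE[key] = s
    return _PREPACE_CACHE[key].copy()


_TUNE_CACHE: dict = {}


def tune_conductivity(
    model: IonicModel,
    target_cv: float = 750.0,
    bcl: float = 1.0,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    rtol: float = 0.01,
    d0: float = 0.15,
    max_iter: int = 8,
) -> float:
    """Tune the diffusivity D (mm^2/ms) so that the control strand conducts
    at ``target_cv`` mm/s at basic cycle length ``bcl`` s.

    Uses the CV ~ sqrt(D) scaling of reaction–diffusion wavefronts as a
    fixed-point predictor (D <- D * (target/CV)^2), which converges in a
    few strand evaluations; each evaluation stimulates one beat on the
    pre-paced strand (the first tissue beat after 50 single-cell beats
    conducts at the steady speed for practical purposes).  Raises if the
    model cannot reach the target.  The cAF variant of the same model
    reuses this D scaled by :data:`CAF_CONDUCTIVITY_FACTOR`.
    """
    if model.variant != "control":
        raise ModelError("conductivity is tuned on the control variant")
    key = (model.key, target_cv, round(bcl, 6), dt, dx)
    if key in _TUNE_CACHE:
        return _TUNE_CACHE[key]
    diff = d0
    cv = float("nan")
    for _ in range(max_iter):
        cv = strand_cv(model, diff, bcl, n_beats=1, dt=dt, dx=dx)
        if abs(cv - target_cv) <= rtol * target_cv:
            _TUNE_CACHE[key] = diff
            return diff
        diff *= (target_cv / cv) ** 2
        if not 1e-4 < diff < 10.0:
            raise ModelError(
                f"{model.key}: cannot reach CV {target_cv} mm/s "
                f"(last CV {cv:.1f} at D {diff:.3g})"
            )
    raise ModelError(
        f"{model.key}: conductivity tuning did not converge (CV {cv:.1f})"
    )


def strand_cv(
    model: IonicModel,
    diffusivity: float,
    bcl: float,
    n_beats: int = 2,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    stim_amp: float | None = None,
) -> float:
    """CV (mm/s) of beat ``n_beats`` on the standard strand seeded with the
    50-beat pre-paced single-cell state."""
    nx = int(round(STRAND_LENGTH_MM / dx))
    s0 = prepace_state(model, bcl, dt=dt)
    states = np.tile(s0, (nx, 1))
    if stim_amp is None:
        thr = find_tissue_threshold(model, states, diffusivity, dt=dt, dx=dx)
        stim_amp = TISSUE_STIM_SCALE * thr
    period = int(round(bcl * 1e3 / dt))
    res = run_strand(
        model, states, diffusivity, n_beats * period, dt=dt, dx=dx,
        stim_amp=stim_amp, stim_period=period, stim_dur=int(round(2.0 / dt)),
        n_stims=n_beats, act_from_step=(n_beats - 1) * period,
    )
    return measure_cv(res.act_t, dx)
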