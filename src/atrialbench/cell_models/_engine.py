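"""Compiled integration kernels shared by all ionic models.

The hot loops (single-cell pacing, voltage clamp, 1D strand and 2D patch
monodomain integration) are numba-compiled once per model.  Stimulus
schedules are expressed in integration steps: a pulse train starting at
``stim_first`` with period ``stim_period`` and width ``stim_dur`` steps,
limited to ``n_stims`` pulses.  All kernels return a negative step index on
NaN (the Python wrappers turn that into a diagnostic error) and clamp gate
states to [0, 1] after every update.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "FASTMATH",
    "make_stepper",
    "build_cell_kernel",
    "build_strand_kernel",
    "build_patch_kernel",
]

#: fastmath flags that keep NaN semantics intact (NaN blow-ups must remain
#: detectable by the kernels' x != x checks).
FASTMATH = {"nsz", "arcp", "contract", "afn", "reassoc"}


def make_stepper(core, n_state: int, gating_index, stiff_index=()):
    """Build a generic ``step`` from a model's ``core`` rate function.

    Gating states are advanced with the Rush–Larsen exponential update
    y <- y_inf + (y - y_inf) * exp(-dt / tau); states in ``stiff_index``
    with a classical RK4 sub-integrator (all other states frozen within the
    step, as used for stiff calcium compartments); everything else with
    forward Euler.  Hand-written per-model steppers are free to bypass this
    factory; plugins get a correct integrator for free.
    """
    is_gate = np.zeros(n_state, dtype=np.bool_)
    is_gate[np.asarray(gating_index, dtype=np.int64)] = True
    stiff = np.asarray(stiff_index, dtype=np.int64)
    is_stiff = np.zeros(n_state, dtype=np.bool_)
    if stiff.size:
        is_stiff[stiff] = True

    @njit(fastmath=FASTMATH)
    def step(state, params, dt, istim, d, yinf, tau):
        core(state, params, istim, d, yinf, tau)
        if stiff.size:
            # RK4 on the stiff subset; k1 from the shared evaluation above.
            k1 = np.empty(stiff.size)
            k2 = np.empty(stiff.size)
            k3 = np.empty(stiff.size)
            k4 = np.empty(stiff.size)
            save = np.empty(stiff.size)
            for a in range(stiff.size):
                save[a] = state[stiff[a]]
                k1[a] = d[stiff[a]]
            for a in range(stiff.size):
                state[stiff[a]] = save[a] + 0.5 * dt * k1[a]
            core(state, params, istim, d, yinf, tau)
            for a in range(stiff.size):
                k2[a] = d[stiff[a]]
                state[stiff[a]] = save[a] + 0.5 * dt * k2[a]
            core(state, params, istim, d, yinf, tau)
            for a in range(stiff.size):
                k3[a] = d[stiff[a]]
                state[stiff[a]] = save[a] + dt * k3[a]
            core(state, params, istim, d, yinf, tau)
            for a in range(stiff.size):
                k4[a] = d[stiff[a]]
                state[stiff[a]] = save[a]
            # restore rates/gate tables at the step's start point
            core(state, params, istim, d, yinf, tau)
            for a in range(stiff.size):
                k4[a] = save[a] + dt / 6.0 * (k1[a] + 2 * k2[a] + 2 * k3[a] + k4[a])
        for i in range(n_state):
            if is_gate[i]:
                y = yinf[i] + (state[i] - yinf[i]) * np.exp(-dt / tau[i])
                if y < 0.0:
                    y = 0.0
                elif y > 1.0:
                    y = 1.0
                state[i] = y
            elif not is_stiff[i]:
                state[i] = state[i] + dt * d[i]
        if stiff.size:
            for a in range(stiff.size):
                state[stiff[a]] = k4[a]

    return step


def build_cell_kernel(step, currents, n_state: int, n_cur: int):
    """Single-cell driver: pacing train, optional voltage clamp, optional
    per-step current-extrema tracking, V/[Ca]i sampling."""

    @njit(fastmath=FASTMATH)
    def run_cell(
        state,
        params,
        dt,
        n_steps,
        stim_amp,
        stim_first,
        stim_period,
        stim_dur,
        n_stims,
        sample_every,
        v_out,
        cai_out,
        cai_idx,
        vhold,
        track_extrema,
        cur_min,
        cur_max,
    ):
        d = np.empty(n_state)
        yinf = np.empty(n_state)
        tau = np.empty(n_state)
        cur = np.empty(n_cur)
        clamp = vhold == vhold  # NaN -> free-running
        ns = 0
        for k in range(n_steps):
            if sample_every > 0 and k % sample_every == 0:
                v_out[ns] = state[0]
                if cai_idx >= 0:
                    cai_out[ns] = state[cai_idx]
                ns += 1
            istim = 0.0
            if stim_period > 0 and k >= stim_first:
                kk = k - stim_first
                if kk // stim_period < n_stims and kk % stim_period < stim_dur:
                    istim = stim_amp
            step(state, params, dt, istim, d, yinf, tau)
            if clamp:
                state[0] = vhold
            if track_extrema:
                currents(state, params, cur)
                for i in range(n_cur):
                    if cur[i] < cur_min[i]:
                        cur_min[i] = cur[i]
                    if cur[i] > cur_max[i]:
                        cur_max[i] = cur[i]
            if state[0] != state[0]:
                return -(k + 1)
        if sample_every > 0 and n_steps % sample_every == 0:
            v_out[ns] = state[0]
            if cai_idx >= 0:
                cai_out[ns] = state[cai_idx]
            ns += 1
        return ns

    return run_cell


def build_strand_kernel(step, currents, n_state: int, n_cur: int):
    """1D monodomain strand: 3-point Laplacian, no-flux ends, stimulus in a
    voxel range, per-voxel activation tracking from ``act_from_step`` on
    (max dV/dt with its two neighbouring slope samples for sub-step
    parabolic refinement, plus max V), and probe-voxel V sampling."""

    @njit(fastmath=FASTMATH)
    def run_strand(
        states,  # (nx, n_state)
        params,
        dt,
        n_steps,
        r_coef,  # D * dt / dx^2
        stim_amp,
        sx0,
        sx1,
        stim_first,
        stim_period,
        stim_dur,
        n_stims,
        act_from_step,
        act_k,  # int64: step index of the max-slope interval, -1 if none
        act_dvdt,
        act_prev,  # slope one step before the max
        act_next,  # slope one step after the max
        act_vmax,
        sample_every,
        probe_idx,
        probe_v,  # (n_frames, n_probes)
    ):
        nx = states.shape[0]
        d = np.empty(n_state)
        yinf = np.empty(n_state)
        tau = np.empty(n_state)
        vold = np.empty(nx)
        lap = np.empty(nx)
        last_dv = np.zeros(nx)
        frame = 0
        for k in range(n_steps):
            if sample_every > 0 and k % sample_every == 0:
                for p in range(probe_idx.size):
                    probe_v[frame, p] = states[probe_idx[p], 0]
                frame += 1
            for i in range(nx):
                vold[i] = states[i, 0]
            lap[0] = vold[1] - vold[0]
            lap[nx - 1] = vold[nx - 2] - vold[nx - 1]
            for i in range(1, nx - 1):
                lap[i] = vold[i - 1] - 2.0 * vold[i] + vold[i + 1]
            stim_on = False
            if stim_period > 0 and k >= stim_first:
                kk = k - stim_first
                if kk // stim_period < n_stims and kk % stim_period < stim_dur:
                    stim_on = True
            for i in range(nx):
                istim = stim_amp if (stim_on and sx0 <= i < sx1) else 0.0
                row = states[i]
                step(row, params, dt, istim, d, yinf, tau)
                v = row[0] + r_coef * lap[i]
                row[0] = v
                if v != v:
                    return -(k + 1)
                if k >= act_from_step:
                    dv = (v - vold[i]) / dt
                    if k == act_k[i] + 1:
                        act_next[i] = dv
                    if dv > act_dvdt[i]:
                        act_prev[i] = last_dv[i]
                        act_dvdt[i] = dv
                        act_next[i] = dv  # provisional until next step
                        act_k[i] = k
                    if v > act_vmax[i]:
                        act_vmax[i] = v
                    last_dv[i] = dv
        if sample_every > 0 and n_steps % sample_every == 0:
            for p in range(probe_idx.size):
                probe_v[frame, p] = states[probe_idx[p], 0]
            frame += 1
        return frame

    return run_strand


def build_patch_kernel(step, currents, n_state: int, n_cur: int):
    """2D monodomain patch: 5-point Laplacian, no-flux boundary, planar S1
    stimulus on the left edge plus one cross-field S2 pulse over the lower
    row block, float32 V_m movie recording."""

    @njit(fastmath=FASTMATH)
    def run_patch(
        states,  # (ny, nx, n_state)
        params,
        dt,
        n_steps,
        r_coef,
        s1_amp,
        s1_cols,
        s1_first,
        s1_period,
        s1_dur,
        n_s1,
        s2_amp,
        s2_first,
        s2_dur,
        s2_rows,  # S2 applied to rows [0, s2_rows)
        sample_every,
        movie,  # float32 (n_frames, ny, nx)
    ):
        ny = states.shape[0]
        nx = states.shape[1]
        d = np.empty(n_state)
        yinf = np.empty(n_state)
        tau = np.empty(n_state)
        vold = np.empty((ny, nx))
        frame = 0
        for k in range(n_steps):
            if sample_every > 0 and k % sample_every == 0:
                for y in range(ny):
                    for x in range(nx):
                        movie[frame, y, x] = states[y, x, 0]
                frame += 1
            for y in range(ny):
                for x in range(nx):
                    vold[y, x] = states[y, x, 0]
            s1_on = False
            if s1_period > 0 and k >= s1_first:
                kk = k - s1_first
                if kk // s1_period < n_s1 and kk % s1_period < s1_dur:
                    s1_on = True
            s2_on = s2_dur > 0 and s2_first <= k < s2_first + s2_dur
            for y in range(ny):
                ym = y - 1 if y > 0 else 1
                yp = y + 1 if y < ny - 1 else ny - 2
                for x in range(nx):
                    xm = x - 1 if x > 0 else 1
                    xp = x + 1 if x < nx - 1 else nx - 2
                    lap = (
                        vold[ym, x]
                        + vold[yp, x]
                        + vold[y, xm]
                        + vold[y, xp]
                        - 4.0 * vold[y, x]
                    )
                    istim = 0.0
                    if s1_on and x < s1_cols:
                        istim = s1_amp
                    if s2_on and y < s2_rows:
                        istim += s2_amp
                    row = states[y, x]
                    step(row, params, dt, istim, d, yinf, tau)
                    v = row[0] + r_coef * lap
                    row[0] = v
                    if v != v:
                        return -(k + 1)
        if sample_every > 0 and n_steps % sample_every == 0:
            for y in range(ny):
                for x in range(nx):
                    movie[frame, y, x] = states[y, x, 0]
            frame += 1
        return frame

    return run_patch
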