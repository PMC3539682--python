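"""Steady-state 1D strand restitution of APD90, CV, ERP and wavelength.

Protocol per basic cycle length (BCL):

1. 50 beats in a single-cell environment adapt the model to the BCL; the
   resulting state seeds every voxel of a 20 mm strand (dx = 0.1 mm).
2. Five consecutive beats are stimulated from one end at 1.2x the tissue
   threshold.  Measurements are valid only if all five beats propagate.
3. APD90 is measured at the voxel three-quarters of the way down the
   strand on beat 5; CV divides the distance between the centers of the
   two strand halves by their beat-5 activation-time difference.
4. ERP: after the final (5th) S1, a premature S2 at the same site scans
   coupling intervals at 1 ms resolution; the ERP is the shortest interval
   whose S2 still produces a propagated AP detected at the center of the
   distal half.  Propagation (vs. electrotonic spread) requires an
   upstroke at the detection site faster than 10% of the S1 upstroke with
   a peak above -20 mV.
5. Wavelength = ERP x CV.

Chronic-AF variants run with the control-tuned diffusivity scaled by 0.70.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell_models import DT_DEFAULT, IonicModel, get_model
from .monodomain_solver import (
    CAF_CONDUCTIVITY_FACTOR,
    DX_DEFAULT,
    STRAND_LENGTH_MM,
    ConductionBlock,
    find_tissue_threshold,
    measure_cv,
    prepace_state,
    run_strand,
    tune_conductivity,
)
from .single_cell_protocols import Trace, extract_ap_features

__all__ = [
    "StrandProtocolResult",
    "RestitutionCurve",
    "model_diffusivity",
    "run_strand_protocol",
    "measure_erp",
    "wavelength",
    "restitution_curve",
    "BCL_GRID",
]

#: BCL grid of the restitution protocols (s).
BCL_GRID = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.25, 0.2)

S1_COUNT = 5
ERP_COARSE_MS = 10
ERP_POST_WINDOW_MS = 250.0  # observation window after S2


def model_diffusivity(
    model: IonicModel,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    target_cv: float = 750.0,
) -> float:
    """Diffusivity for a model variant: tuned on the control model at BCL
    1 s, scaled by 0.70 for the chronic-AF variant."""
    control = get_model(model.name) if model.variant != "control" else model
    d = tune_conductivity(control, target_cv=target_cv, dt=dt, dx=dx)
    return d * CAF_CONDUCTIVITY_FACTOR if model.variant == "caf" else d


_STIM_AMP_CACHE: dict = {}


def tissue_stim_amp(
    model: IonicModel,
    diffusivity: float,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
) -> float:
    """Per-model strand stimulus amplitude: 1.2x the tissue threshold
    measured on the strand seeded with the BCL 1 s pre-paced state.

    The amplitude is adapted once per model/variant (not per cycle
    length), so at fast pacing the fixed stimulus may fail to capture
    partially refractory tissue — which is itself a measured outcome of
    the restitution protocol."""
    key = (model.key, round(diffusivity, 9), dt, dx)
    if key not in _STIM_AMP_CACHE:
        nx = int(round(STRAND_LENGTH_MM / dx))
        states = np.tile(prepace_state(model, 1.0, dt=dt), (nx, 1))
        thr = find_tissue_threshold(model, states, diffusivity, dt=dt, dx=dx)
        _STIM_AMP_CACHE[key] = 1.2 * thr
    return _STIM_AMP_CACHE[key]


@dataclass
class StrandProtocolResult:
    """Beat-5 strand measurements at one BCL."""

    bcl: float  # s
    apd90: float  # ms (NaN if undefined)
    cv: float  # mm/s (NaN if blocked)
    capture: bool  # all 5 beats propagated to the distal site
    failed_beat: int | None  # first non-propagated beat (1-based), if any
    stim_amp: float  # pA/pF
    diffusivity: float  # mm^2/ms
    s1_dvdt_distal: float  # V/s, beat-5 upstroke at the ERP detection site
    pre_s5_states: np.ndarray | None  # strand state just before the 5th S1
    act_t: np.ndarray | None = None


def run_strand_protocol(
    model: IonicModel,
    bcl: float,
    *,
    diffusivity: float | None = None,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
    keep_states: bool = True,
) -> StrandProtocolResult:
    """Run the 5-beat strand protocol at one BCL (s); see module docstring."""
    if diffusivity is None:
        diffusivity = model_diffusivity(model, dt=dt, dx=dx)
    nx = int(round(STRAND_LENGTH_MM / dx))
    site_apd = 3 * nx // 4  # three-quarters down the strand
    site_cv1, site_cv2 = nx // 4, 3 * nx // 4
    stim_amp = tissue_stim_amp(model, diffusivity, dt=dt, dx=dx)
    s0 = prepace_state(model, bcl, dt=dt)
    states = np.tile(s0, (nx, 1))
    period = int(round(bcl * 1e3 / dt))
    dur = int(round(2.0 / dt))
    sample_every = max(1, int(round(0.05 / dt)))

    # beats 1..4, recording the distal probe to verify capture of each beat
    res4 = run_strand(
        model, states, diffusivity, (S1_COUNT - 1) * period, dt=dt, dx=dx,
        stim_amp=stim_amp, stim_period=period, stim_dur=dur,
        n_stims=S1_COUNT - 1, probe_idx=(site_apd,), sample_every=sample_every,
    )
    pre_s5 = states.copy() if keep_states else None
    # beat 5 with activation tracking
    res5 = run_strand(
        model, states, diffusivity, period, dt=dt, dx=dx,
        stim_amp=stim_amp, stim_period=period, stim_dur=dur, n_stims=1,
        act_from_step=0, probe_idx=(site_apd,), sample_every=sample_every,
    )

    # capture check: one upstroke crossing -20 mV per beat at the distal site
    failed = None
    for b in range(S1_COUNT - 1):
        k0 = int(round(b * bcl * 1e3 / res4.probe_dt))
        k1 = int(round((b + 1) * bcl * 1e3 / res4.probe_dt))
        seg = res4.probe_v[k0:k1, 0]
        if seg.size == 0 or np.max(seg) < -20.0:
            failed = b + 1
            break
    if failed is None and res5.act_vmax[site_apd] < -20.0:
        failed = S1_COUNT
    capture = failed is None

    apd90 = cv = math.nan
    s1_dvdt = float(res5.act_dvdt[site_apd])
    if capture:
        probe_trace = Trace(
            t0=0.0,
            dt_sample=res5.probe_dt,
            v=res5.probe_v[:, 0],
            cai=None,
            stim_times=np.array([0.0]),
        )
        apd90 = extract_ap_features(probe_trace, 0).apd90
        try:
            cv = measure_cv(res5.act_t, dx, site_cv1, site_cv2)
        except ConductionBlock:
            cv = math.nan
    return StrandProtocolResult(
        bcl=bcl,
        apd90=apd90,
        cv=cv,
        capture=capture,
        failed_beat=failed,
        stim_amp=stim_amp,
        diffusivity=diffusivity,
        s1_dvdt_distal=s1_dvdt,
        pre_s5_states=pre_s5,
        act_t=res5.act_t,
    )


class _S1Timeline:
    """States of the strand at 1 ms resolution after the final S1.

    The S1 response segment is shared by every S2 trial, so it is advanced
    once (snapshotting each millisecond) and each coupling-interval trial
    only simulates the post-S2 observation window.
    """

    def __init__(self, model, proto, dt, dx):
        self.model = model
        self.proto = proto
        self.dt = dt
        self.dx = dx
        self.states_by_ms: dict[int, np.ndarray] = {
            0: proto.pre_s5_states.copy()
        }
        self._rolling = proto.pre_s5_states.copy()
        self._t_ms = 0
        self.steps_per_ms = int(round(1.0 / dt))

    def at(self, t_ms: int) -> np.ndarray:
        while self._t_ms < t_ms:
            # S1 pulse occupies the first 2 ms of the segment
            in_pulse = self._t_ms < 2
            run_strand(
                self.model, self._rolling, self.proto.diffusivity,
                self.steps_per_ms, dt=self.dt, dx=self.dx,
                stim_amp=self.proto.stim_amp if in_pulse else 0.0,
                stim_period=self.steps_per_ms + 1 if in_pulse else 0,
                stim_dur=self.steps_per_ms, n_stims=1 if in_pulse else 0,
            )
            self._t_ms += 1
            self.states_by_ms[self._t_ms] = self._rolling.copy()
        return self.states_by_ms[t_ms].copy()

    def s2_propagates(self, interval_ms: int) -> bool:
        states = self.at(interval_ms)
        nx = states.shape[0]
        site = 3 * nx // 4
        n_steps = int(round(ERP_POST_WINDOW_MS / self.dt))
        res = run_strand(
            self.model, states, self.proto.diffusivity, n_steps,
            dt=self.dt, dx=self.dx,
            stim_amp=self.proto.stim_amp, stim_period=n_steps + 1,
            stim_dur=int(round(2.0 / self.dt)), n_stims=1,
            act_from_step=int(round(2.0 / self.dt)),
        )
        return bool(
            res.act_vmax[site] > -20.0
            and res.act_dvdt[site] > 0.1 * self.proto.s1_dvdt_distal
            and res.act_t[site] >= 0
        )


def measure_erp(
    model: IonicModel,
    bcl: float,
    proto: StrandProtocolResult | None = None,
    *,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
) -> float:
    """Effective refractory period (ms) on the strand at one BCL.

    Scans the S1-S2 coupling interval at 10 ms resolution (starting near
    the beat-5 APD90 and expanding as needed) and then bisects to 1 ms;
    returns the shortest interval that still conducts to the distal
    detection site.  Raises :class:`ConductionBlock` if even S2 = BCL fails
    ("ERP >= BCL").
    """
    if proto is None:
        proto = run_strand_protocol(model, bcl, dt=dt, dx=dx)
    if not proto.capture or proto.pre_s5_states is None:
        raise ConductionBlock(
            f"{model.key}: S1 train did not capture at BCL {bcl}"
        )
    tl = _S1Timeline(model, proto, dt, dx)
    bcl_ms = int(round(bcl * 1e3))
    # first propagating interval, searching upward from near APD90 if needed
    hi = bcl_ms
    if math.isfinite(proto.apd90):
        start = min(bcl_ms, ERP_COARSE_MS * int((proto.apd90 + 100.0) / ERP_COARSE_MS))
        ci = start
        while not tl.s2_propagates(ci):
            ci += ERP_COARSE_MS
            if ci >= bcl_ms:
                if not tl.s2_propagates(bcl_ms):
                    raise ConductionBlock(
                        f"{model.key}: ERP >= BCL at BCL {bcl}"
                    )
                ci = bcl_ms
                break
        hi = ci
    elif not tl.s2_propagates(bcl_ms):
        raise ConductionBlock(f"{model.key}: ERP >= BCL at BCL {bcl}")
    # coarse descent to bracket the block
    lo = None
    ci = hi - ERP_COARSE_MS
    while ci > 0:
        if not tl.s2_propagates(ci):
            lo = ci
            break
        hi = ci
        ci -= ERP_COARSE_MS
    if lo is None:
        lo = 0
    # 1 ms bisection
    while hi - lo > 1:
        mid = (hi + lo) // 2
        if tl.s2_propagates(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def wavelength(erp_ms: float, cv_mm_s: float) -> float:
    """Wavelength (mm) = ERP x CV; NaN if either input is undefined."""
    if math.isnan(erp_ms) or math.isnan(cv_mm_s):
        return math.nan
    return erp_ms * 1e-3 * cv_mm_s


@dataclass
class RestitutionCurve:
    """BCL-indexed strand restitution measurements."""

    model: str
    records: list[dict]

    def as_rows(self) -> list[dict]:
        return self.records


def restitution_curve(
    model: IonicModel,
    bcl_grid=BCL_GRID,
    *,
    with_erp: bool = True,
    dt: float = DT_DEFAULT,
    dx: float = DX_DEFAULT,
) -> RestitutionCurve:
    """Full restitution curve over a BCL grid.

    Each record carries {bcl, apd90, cv, erp, wl, capture, reason}; failed
    entries keep NaN measurements and the failure reason.  The wavelength
    is the exact product ERP x CV wherever both are defined.
    """
    records = []
    for bcl in bcl_grid:
        rec = {
            "bcl": bcl, "apd90": math.nan, "cv": math.nan,
            "erp": math.nan, "wl": math.nan, "capture": False, "reason": "",
        }
        proto = run_strand_protocol(model, bcl, dt=dt, dx=dx)
        rec["capture"] = proto.capture
        if not proto.capture:
            rec["reason"] = f"capture failure at beat {proto.failed_beat}"
        else:
            rec["apd90"] = proto.apd90
            rec["cv"] = proto.cv
            if with_erp:
                try:
                    rec["erp"] = measure_erp(model, bcl, proto, dt=dt, dx=dx)
                except ConductionBlock as e:
                    rec["reason"] = str(e)
            rec["wl"] = wavelength(rec["erp"], rec["cv"])
        records.append(rec)
    return RestitutionCurve(model=model.key, records=records)
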