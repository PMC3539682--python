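"""Single-cell experiments: pacing, feature extraction, stability, alternans.

The measurement conventions used throughout:

* RMP is V_m sampled just before the stimulus of the beat in question.
* AP amplitude is peak V_m minus RMP.
* APD_x is the interval from the time of maximum upstroke velocity to the
  first crossing of (peak - x% * amplitude) on the repolarizing limb; if the
  AP never reaches that level before the next stimulus the value is
  undefined (NaN) — which happens physiologically at short cycle lengths.
* The calcium transient is characterised by its pre-stimulus (diastolic)
  level and its peak-minus-diastolic amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell_models import DT_DEFAULT, IonicModel, _run_cell, find_threshold

__all__ = [
    "Trace",
    "APFeatures",
    "StabilityRecord",
    "pace",
    "extract_ap_features",
    "beat_features",
    "long_term_stability",
    "restitution_single_cell",
    "detect_alternans",
]


@dataclass
class Trace:
    """Uniformly sampled single-cell recording."""

    t0: float  # ms
    dt_sample: float  # ms
    v: np.ndarray  # mV
    cai: np.ndarray | None  # mM (None if the model has no [Ca2+]_i)
    stim_times: np.ndarray  # ms, pulse onsets
    stim_duration: float = 2.0  # ms

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt_sample * np.arange(self.v.size)

    def index_of(self, t: float) -> int:
        return int(round((t - self.t0) / self.dt_sample))


@dataclass
class APFeatures:
    """Scalar descriptors of one action potential / calcium transient."""

    amplitude: float  # mV (peak - RMP)
    rmp: float  # mV
    apd50: float  # ms (NaN if 50% repolarization not reached)
    apd90: float  # ms (NaN if 90% repolarization not reached)
    dvdt_max: float  # V/s
    t_upstroke: float  # ms, time of dV/dt_max
    v_peak: float  # mV
    cat_diastolic: float = math.nan  # uM
    cat_amplitude: float = math.nan  # uM
    captured: bool = True  # stimulus elicited an AP


@dataclass
class StabilityRecord:
    """Per-beat features of a long run plus a quiescent-phase RMP series."""

    beat_times: np.ndarray  # s, stimulus onsets
    apd50: np.ndarray
    apd90: np.ndarray
    amplitude: np.ndarray
    rmp: np.ndarray
    quiescent_t: np.ndarray = field(default_factory=lambda: np.empty(0))  # s
    quiescent_rmp: np.ndarray = field(default_factory=lambda: np.empty(0))


def pace(
    model: IonicModel,
    bcl: float = 1.0,
    duration: float = 50.0,
    stim_scale: float = 2.0,
    stim_amp: float | None = None,
    state=None,
    dt: float = DT_DEFAULT,
    dt_sample: float = 0.05,
    pulse_duration: float = 2.0,
    return_state: bool = False,
):
    """Pace a single cell at basic cycle length ``bcl`` (s) for ``duration``
    (s) and record V_m (and [Ca2+]_i).

    The stimulus is a rectangular 2 ms pulse at ``stim_scale`` times the
    diastolic threshold measured from the protocol's starting state (pass
    ``stim_amp`` in pA/pF to skip the threshold search).  If ``duration``
    is shorter than ``bcl``, exactly one stimulus is delivered.
    """
    s = np.array(model.initial_state if state is None else state, dtype=float)
    if stim_amp is None:
        stim_amp = stim_scale * find_threshold(
            model, pulse_duration, state=s, dt=dt
        )
    period = int(round(bcl * 1000.0 / dt))
    n_steps = int(round(duration * 1000.0 / dt))
    n_stims = n_steps // period + (1 if n_steps % period > 0 else 0)
    sample_every = max(1, int(round(dt_sample / dt)))
    v, cai, _, _ = _run_cell(
        model, s, dt, n_steps,
        stim_amp=stim_amp,
        stim_period=period,
        stim_dur=int(round(pulse_duration / dt)),
        n_stims=n_stims,
        sample_every=sample_every,
    )
    stim_times = np.arange(n_stims) * (period * dt)
    trace = Trace(
        t0=0.0,
        dt_sample=sample_every * dt,
        v=v,
        cai=cai if model.cai_index >= 0 else None,
        stim_times=stim_times,
        stim_duration=pulse_duration,
    )
    return (trace, s) if return_state else trace


def extract_ap_features(trace: Trace, beat_index: int = -1) -> APFeatures:
    """Measure one beat of a paced trace.

    ``beat_index`` refers to the stimuli in ``trace.stim_times`` (negative
    indices count from the end).  Raises ``ValueError`` when the trace
    contains no beat or no AP is detected (constant/degenerate input).
    """
    n_beats = len(trace.stim_times)
    if n_beats == 0:
        raise ValueError("trace contains no stimuli")
    if beat_index < 0:
        beat_index += n_beats
    if not 0 <= beat_index < n_beats:
        raise ValueError(f"beat {beat_index} outside 0..{n_beats - 1}")
    t_stim = trace.stim_times[beat_index]
    i0 = trace.index_of(t_stim)
    i1 = (
        trace.index_of(trace.stim_times[beat_index + 1])
        if beat_index + 1 < n_beats
        else trace.v.size
    )
    if i1 - i0 < 4:
        raise ValueError("beat not fully contained in trace")
    seg = trace.v[i0:i1]
    h = trace.dt_sample
    rmp = float(trace.v[max(i0 - 1, 0)])
    dvdt = np.diff(seg) / h  # mV/ms = V/s
    iup = int(np.argmax(dvdt))
    dvdt_max = float(dvdt[iup])
    t_up = t_stim + (iup + 0.5) * h
    ipk = int(np.argmax(seg))
    v_peak = float(seg[ipk])
    amplitude = v_peak - rmp
    # a regenerative response overshoots any passive stimulus artifact; at
    # very short cycle lengths real APs may peak below 0 mV, so capture is
    # peak above -40 mV with a genuine upstroke
    captured = v_peak > -40.0 and amplitude > 30.0 and dvdt_max > 5.0
    if not captured and amplitude < 5.0:
        raise ValueError("no AP detected in beat window")

    def apd(frac: float) -> float:
        level = v_peak - frac * amplitude
        below = np.flatnonzero(seg[ipk:] <= level)
        if below.size == 0:
            return math.nan
        k = ipk + below[0]
        if k == 0:
            return math.nan
        # linear interpolation of the crossing
        v1, v2 = seg[k - 1], seg[k]
        f = (v1 - level) / (v1 - v2) if v2 != v1 else 0.0
        t_cross = t_stim + (k - 1 + f) * h
        return float(t_cross - t_up)

    feats = APFeatures(
        amplitude=amplitude,
        rmp=rmp,
        apd50=apd(0.50),
        apd90=apd(0.90),
        dvdt_max=dvdt_max,
        t_upstroke=float(t_up),
        v_peak=v_peak,
        captured=captured,
    )
    if trace.cai is not None:
        cseg = trace.cai[i0:i1]
        dia = float(trace.cai[max(i0 - 1, 0)])
        feats.cat_diastolic = dia * 1e3  # mM -> uM
        feats.cat_amplitude = (float(np.max(cseg)) - dia) * 1e3
    return feats


def beat_features(trace: Trace) -> list[APFeatures]:
    """Features of every complete beat (undetected APs marked uncaptured)."""
    out = []
    for b in range(len(trace.stim_times)):
        try:
            out.append(extract_ap_features(trace, b))
        except ValueError:
            out.append(
                APFeatures(
                    amplitude=math.nan, rmp=math.nan, apd50=math.nan,
                    apd90=math.nan, dvdt_max=math.nan, t_upstroke=math.nan,
                    v_peak=math.nan, captured=False,
                )
            )
    return out


def long_term_stability(
    model: IonicModel,
    paced_minutes: float = 20.0,
    quiescent_minutes: float = 0.0,
    bcl: float = 1.0,
    dt: float = DT_DEFAULT,
    dt_sample: float = 0.1,
) -> StabilityRecord:
    """Long-run characterisation: optional quiescent phase with continuous
    RMP sampling, then pacing with per-beat APD/amplitude series.

    The two schedules of interest are ``paced_minutes=20`` (APD and
    amplitude drift) and ``quiescent_minutes=20, paced_minutes=10`` (RMP
    drift and the quiescent-to-paced transition).
    """
    state = np.array(model.initial_state, dtype=float)
    qt = qrmp = np.empty(0)
    if quiescent_minutes > 0:
        n_steps = int(round(quiescent_minutes * 60e3 / dt))
        sample_every = int(round(1000.0 / dt))  # 1 Hz
        v, _, _, _ = _run_cell(model, state, dt, n_steps, sample_every=sample_every)
        qt = np.arange(v.size) * (sample_every * dt) / 1e3
        qrmp = v
    if paced_minutes > 0:
        trace = pace(
            model, bcl=bcl, duration=paced_minutes * 60.0, state=state,
            dt=dt, dt_sample=dt_sample,
        )
        feats = beat_features(trace)
        t_offset = quiescent_minutes * 60.0
        return StabilityRecord(
            beat_times=trace.stim_times / 1e3 + t_offset,
            apd50=np.array([f.apd50 for f in feats]),
            apd90=np.array([f.apd90 for f in feats]),
            amplitude=np.array([f.amplitude for f in feats]),
            rmp=np.array([f.rmp for f in feats]),
            quiescent_t=qt,
            quiescent_rmp=qrmp,
        )
    return StabilityRecord(
        beat_times=np.empty(0), apd50=np.empty(0), apd90=np.empty(0),
        amplitude=np.empty(0), rmp=np.empty(0),
        quiescent_t=qt, quiescent_rmp=qrmp,
    )


def restitution_single_cell(
    model: IonicModel,
    bcl_grid=(1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.25, 0.2),
    duration: float = 30.0,
    steady_window: float = 10.0,
    dt: float = DT_DEFAULT,
) -> dict[float, dict]:
    """Single-cell APD_50 restitution with alternans classification.

    Each BCL is run independently for ``duration`` s from the model's
    published initial state; the last ``steady_window`` s of beats are kept
    (APD_50 is the metric — at short cycle lengths some APs never reach 90%
    repolarization).  Returns ``{bcl: {"apd50": array, "pattern": str,
    "amplitude": float}}``.
    """
    out = {}
    for bcl in bcl_grid:
        trace = pace(model, bcl=bcl, duration=duration, dt=dt)
        feats = beat_features(trace)
        t_cut = (duration - steady_window) * 1e3
        tail = [
            f for f, ts in zip(feats, trace.stim_times)
            if ts >= t_cut and f.captured
        ]
        apd50 = np.array([f.apd50 for f in tail])
        pattern, amp = detect_alternans(apd50)
        out[bcl] = {
            "apd50": apd50,
            "pattern": pattern,
            "amplitude": amp,
            "n_capture_failures": sum(not f.captured for f in feats),
        }
    return out


def detect_alternans(
    apd_sequence,
    threshold: float = 2.0,
) -> tuple[str, float]:
    """Classify a steady-state APD sequence.

    Returns ``(pattern, amplitude)`` with pattern one of ``"none"``,
    ``"period-2"``, ``"period-3"`` or ``"irregular"``.  Beat-to-beat
    variation below ``threshold`` ms counts as numerically constant.  For
    period-2 the amplitude is the mean |APD_n - APD_{n+1}|; for period-3
    the spread of the 3-beat cycle.  Classification folds the detrended
    sequence modulo the candidate period and compares within-phase spread
    to between-phase separation.
    """
    x = np.asarray(apd_sequence, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise ValueError("need at least 8 steady-state beats")
    diffs = np.diff(x)
    if float(np.max(np.abs(diffs))) < threshold:
        return "none", 0.0
    # period-2: essentially every beat-to-beat difference is significant
    # and successive differences keep flipping sign (occasional phase
    # slips tolerated); higher periods leave quiet beats inside each cycle
    sig_frac = float(np.mean(np.abs(diffs) >= 0.5 * threshold))
    prod = diffs[:-1] * diffs[1:]
    alt_frac = float(np.mean(prod < 0.0))
    if alt_frac >= 0.7 and sig_frac >= 0.75:
        return "period-2", float(np.mean(np.abs(diffs)))
    # period-3: fold the drift-corrected sequence into 3-beat cycles and
    # compare between-phase separation to within-phase spread
    idx = np.arange(x.size)
    detr = x - np.polyval(np.polyfit(idx, x, 1), idx)
    n = (x.size // 3) * 3
    folded = detr[x.size - n:].reshape(-1, 3)
    within = float(np.mean(np.std(folded, axis=0)))
    between = float(np.ptp(np.mean(folded, axis=0)))
    if between / (within + 0.25) > 2.0 and between > threshold:
        return "period-3", between
    return "irregular", float(np.mean(np.abs(diffs)))
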