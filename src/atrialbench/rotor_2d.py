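"""2D patch arrhythmia experiments: S1-S2 cross-field rotor initiation,
phase-singularity tracking, pseudo-ECG synthesis, dominant frequency.

Phase is the analytic-signal (Hilbert-transform) angle of each voxel's
mean-subtracted V_m series; a time-delay-embedding variant is provided for
cross-checks.  A phase singularity sits on a 2x2 plaquette whose discrete
line integral of wrapped phase differences is +-2*pi; its topological
charge is the winding sign.  Singularities are linked into trajectories by
nearest-neighbour association between consecutive frames.

The pseudo-ECG evaluates, for two virtual electrodes above the patch, the
infinite-volume-conductor potential Phi(e) = sum_vox lap(V_m)/|r_vox - e|
(the divergence of the intercellular current density, up to a constant
prefactor that cancels in the two-electrode difference signal and is
irrelevant to its spectrum); the signal is Phi(e1) - Phi(e2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .cell_models import DT_DEFAULT, IonicModel
from .monodomain_solver import (
    DX_DEFAULT,
    VmMovie,
    find_tissue_threshold,
    prepace_state,
    run_patch,
)

__all__ = [
    "SingularityTrack",
    "PseudoECG",
    "RotorOutcome",
    "compute_phase",
    "compute_phase_embedding",
    "frame_singularities",
    "track_singularities",
    "pseudo_ecg",
    "dominant_frequency",
    "s1s2_cross_field",
]


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------

def compute_phase(movie: VmMovie, amp_floor: float = 1.0) -> np.ndarray:
    """Per-voxel phase in (-pi, pi] from the analytic signal of the
    mean-subtracted V_m series.

    Voxels whose peak-to-peak V_m excursion is below ``amp_floor`` (mV)
    have no defined oscillation phase and are returned as NaN.  The movie
    must span at least two rotation periods for a meaningful phase.
    """
    v = np.asarray(movie.data, dtype=np.float64)
    centered = v - v.mean(axis=0)
    phase = np.angle(hilbert(centered, axis=0))
    quiet = np.ptp(v, axis=0) < amp_floor
    phase[:, quiet] = np.nan
    return phase


def compute_phase_embedding(
    movie: VmMovie, delay_ms: float, amp_floor: float = 1.0
) -> np.ndarray:
    """Time-delay-embedding phase variant: atan2(V(t - tau) - <V>,
    V(t) - <V>), which rotates in the same sense as the analytic-signal
    phase.  Used as an independent cross-check; the leading ``delay``
    frames are NaN."""
    v = np.asarray(movie.data, dtype=np.float64)
    lag = max(1, int(round(delay_ms / movie.dt)))
    c = v - v.mean(axis=0)
    phase = np.full_like(c, np.nan)
    phase[lag:] = np.arctan2(c[:-lag], c[lag:])
    quiet = np.ptp(v, axis=0) < amp_floor
    phase[:, quiet] = np.nan
    return phase


# ---------------------------------------------------------------------------
# singularities
# ---------------------------------------------------------------------------

def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def frame_singularities(phase: np.ndarray, dx: float) -> list[tuple[float, float, int]]:
    """Phase singularities of one phase frame.

    Sums the wrapped phase differences around every elementary 2x2
    plaquette; a winding of +-2*pi marks a singularity of that charge at
    the plaquette center.  Returns (x_mm, y_mm, charge) tuples; plaquettes
    touching undefined (NaN) phase are skipped.
    """
    p = np.asarray(phase)
    a = p[:-1, :-1]
    b = p[:-1, 1:]
    c = p[1:, 1:]
    d = p[1:, :-1]
    winding = (_wrap(b - a) + _wrap(c - b) + _wrap(d - c) + _wrap(a - d)) / (
        2.0 * np.pi
    )
    with np.errstate(invalid="ignore"):
        charge = np.where(np.isnan(winding), 0, np.rint(winding)).astype(int)
    ys, xs = np.nonzero(charge)
    return [
        ((x + 0.5) * dx, (y + 0.5) * dx, int(charge[y, x]))
        for y, x in zip(ys, xs)
    ]


@dataclass
class SingularityTrack:
    """One phase-singularity trajectory."""

    track_id: int
    charge: int
    t: list = field(default_factory=list)  # ms
    x: list = field(default_factory=list)  # mm
    y: list = field(default_factory=list)  # mm

    @property
    def duration(self) -> float:
        return self.t[-1] - self.t[0] if self.t else 0.0

    def bounding_box(self) -> tuple[float, float, float, float]:
        return (min(self.x), min(self.y), max(self.x), max(self.y))

    def area(self) -> float:
        """Bounding-box area of the trajectory (mm^2)."""
        x0, y0, x1, y1 = self.bounding_box()
        return (x1 - x0) * (y1 - y0)


def track_singularities(
    phases: np.ndarray,
    dt: float,
    dx: float,
    linking_radius: float = 2.0,
    t0: float = 0.0,
) -> list[SingularityTrack]:
    """Link per-frame singularities into trajectories.

    ``phases`` is (nt, ny, nx); ``linking_radius`` (mm) is the maximum
    frame-to-frame displacement for track continuation (same charge only).
    """
    tracks: list[SingularityTrack] = []
    active: list[SingularityTrack] = []
    next_id = 0
    for k in range(phases.shape[0]):
        t = t0 + k * dt
        found = frame_singularities(phases[k], dx)
        used = [False] * len(found)
        still_active = []
        for tr in active:
            best, best_d = None, linking_radius
            for i, (x, y, q) in enumerate(found):
                if used[i] or q != tr.charge:
                    continue
                dist = math.hypot(x - tr.x[-1], y - tr.y[-1])
                if dist <= best_d:
                    best, best_d = i, dist
            if best is not None:
                x, y, _ = found[best]
                used[best] = True
                tr.t.append(t)
                tr.x.append(x)
                tr.y.append(y)
                still_active.append(tr)
        active = still_active
        for i, (x, y, q) in enumerate(found):
            if not used[i]:
                tr = SingularityTrack(track_id=next_id, charge=q)
                next_id += 1
                tr.t.append(t)
                tr.x.append(x)
                tr.y.append(y)
                tracks.append(tr)
                active.append(tr)
    return tracks


# ---------------------------------------------------------------------------
# pseudo-ECG and dominant frequency
# ---------------------------------------------------------------------------

@dataclass
class PseudoECG:
    """Two-electrode difference signal (arbitrary units)."""

    t: np.ndarray  # ms
    signal: np.ndarray
    electrodes: tuple  # ((x,y,z), (x,y,z)) in mm

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1e3 / (self.t[1] - self.t[0])


def _laplacian_2d(v: np.ndarray) -> np.ndarray:
    """5-point Laplacian with the solver's mirror (no-flux) boundaries,
    applied framewise to (nt, ny, nx)."""
    p = np.pad(v, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    return (
        p[:, :-2, 1:-1] + p[:, 2:, 1:-1] + p[:, 1:-1, :-2] + p[:, 1:-1, 2:]
        - 4.0 * v
    )


def pseudo_ecg(
    movie: VmMovie,
    electrodes=None,
    height_mm: float = 5.0,
    separation_mm: float = 10.0,
) -> PseudoECG:
    """Pseudo-ECG from a 2D V_m movie.

    Default electrode geometry: both 5 mm above the patch plane, 10 mm
    apart along x, centered on the patch.  Raises ``ValueError`` for an
    electrode placed in the tissue plane (z = 0 inside the patch).
    """
    nt, ny, nx = movie.data.shape
    lx, ly = nx * movie.dx, ny * movie.dx
    if electrodes is None:
        cx, cy = lx / 2.0, ly / 2.0
        electrodes = (
            (cx - separation_mm / 2.0, cy, height_mm),
            (cx + separation_mm / 2.0, cy, height_mm),
        )
    xs = (np.arange(nx) + 0.5) * movie.dx
    ys = (np.arange(ny) + 0.5) * movie.dx
    gx, gy = np.meshgrid(xs, ys)
    weights = []
    for ex, ey, ez in electrodes:
        if ez == 0.0 and 0.0 <= ex <= lx and 0.0 <= ey <= ly:
            raise ValueError("electrode lies inside the tissue plane")
        r = np.sqrt((gx - ex) ** 2 + (gy - ey) ** 2 + ez**2)
        weights.append(1.0 / r)
    lap = _laplacian_2d(np.asarray(movie.data, dtype=np.float64))
    phi = [np.tensordot(lap, w, axes=([1, 2], [0, 1])) for w in weights]
    return PseudoECG(
        t=movie.t, signal=phi[0] - phi[1], electrodes=tuple(electrodes)
    )


def dominant_frequency(
    signal,
    fs: float | None = None,
    band: tuple[float, float] = (1.0, 30.0),
    resolution: float = 0.1,
) -> float:
    """Dominant frequency (Hz): location of the largest spectral peak of
    the mean-removed, Hann-windowed signal within ``band``, zero-padded to
    at least ``resolution`` Hz bin spacing.

    Accepts a :class:`PseudoECG` or a plain array plus ``fs`` (Hz).
    Raises ``ValueError`` on a flat signal ("no oscillation").
    """
    if isinstance(signal, PseudoECG):
        fs = signal.fs
        signal = signal.signal
    if fs is None:
        raise ValueError("fs required for array input")
    x = np.asarray(signal, dtype=np.float64)
    scale = float(np.max(np.abs(x))) if x.size else 0.0
    x = x - x.mean()
    # flat up to round-off counts as no oscillation
    if np.ptp(x) <= 1e-9 * (scale + 1e-30):
        raise ValueError("no oscillation in signal")
    n = x.size
    nfft = max(n, int(round(fs / resolution)))
    spec = np.abs(np.fft.rfft(x * np.hanning(n), n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise ValueError("band outside spectral range")
    if not np.any(spec[sel] > 0):
        raise ValueError("no oscillation in band")
    return float(freqs[sel][np.argmax(spec[sel])])


# ---------------------------------------------------------------------------
# S1-S2 cross-field protocol
# ---------------------------------------------------------------------------

@dataclass
class RotorOutcome:
    """Result of one cross-field rotor-initiation attempt."""

    movie: VmMovie
    s2_offset_ms: float
    success: bool
    tracks: list  # SingularityTrack list, from S2 onward
    phase: np.ndarray | None = None


def s1s2_cross_field(
    model: IonicModel,
    diffusivity: float,
    *,
    patch_mm: float = 100.0,
    dx: float = DX_DEFAULT,
    bcl: float = 0.4,
    n_s1: int = 4,
    s2_offset_ms: float = 180.0,
    observe_ms: float = 1500.0,
    persist_ms: float = 1000.0,
    dt: float = DT_DEFAULT,
    sample_ms: float = 5.0,
    s2_scale: float = 1.0,
    stim_amp: float | None = None,
) -> RotorOutcome:
    """Cross-field (S1-S2) rotor initiation on an isotropic square patch.

    A 50-beat single-cell pre-pacing at ``bcl`` (s) seeds the patch;
    ``n_s1`` planar beats are stimulated from the left edge; one S2 is
    applied to the lower half of the patch ``s2_offset_ms`` after the last
    S1 onset (the model-specific vulnerable-window timing), and the patch
    is observed for ``observe_ms``.  Initiation succeeds when a phase
    singularity persists for ``persist_ms`` after S2.  The full
    100x100 mm, >= 4 s protocol is an offline reproduction mode; scaled
    patches (smaller ``patch_mm``, coarser ``dx``, reduced ``diffusivity``)
    run at desk scale with identical code.
    """
    n = int(round(patch_mm / dx))
    s0 = prepace_state(model, bcl, dt=dt)
    if stim_amp is None:
        # threshold measured on an equivalent strand (same dx/diffusivity)
        strand_states = np.tile(s0, (max(n, 60), 1))
        thr = find_tissue_threshold(model, strand_states, diffusivity, dt=dt, dx=dx)
        stim_amp = 1.2 * thr
    states = np.tile(s0, (n, n, 1))
    period = int(round(bcl * 1e3 / dt))
    dur = int(round(2.0 / dt))
    s2_first = (n_s1 - 1) * period + int(round(s2_offset_ms / dt))
    n_steps = (n_s1 - 1) * period + int(round((s2_offset_ms + observe_ms) / dt))
    movie = run_patch(
        model, states, diffusivity, n_steps, dt=dt, dx=dx,
        s1_amp=stim_amp, s1_period=period, s1_dur=dur, n_s1=n_s1,
        s2_amp=s2_scale * stim_amp, s2_first=s2_first, s2_dur=dur,
        s2_rows=n // 2,
        sample_every=max(1, int(round(sample_ms / dt))),
    )
    t_s2 = s2_first * dt
    k_s2 = int(t_s2 / movie.dt)
    post = VmMovie(
        data=movie.data[k_s2:], dt=movie.dt, dx=dx, t0=t_s2
    )
    phase = compute_phase(post)
    tracks = track_singularities(
        phase, dt=post.dt, dx=dx, linking_radius=4.0 * max(1.0, post.dt / 5.0),
        t0=t_s2,
    )
    last_ps = max((tr.t[-1] for tr in tracks), default=-np.inf)
    success = bool(last_ps - t_s2 >= persist_ms)
    return RotorOutcome(
        movie=movie,
        s2_offset_ms=s2_offset_ms,
        success=success,
        tracks=tracks,
        phase=phase,
    )
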