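"""Phase computation, singularity detection/tracking, pseudo-ECG and
dominant frequency on synthetic fields with known ground truth."""

import numpy as np
import pytest

from atrialbench.monodomain_solver import VmMovie
from atrialbench.rotor_2d import (
    compute_phase,
    compute_phase_embedding,
    dominant_frequency,
    frame_singularities,
    pseudo_ecg,
    track_singularities,
)
from atrialbench.synthetic_fixtures import (
    make_plane_wave_movie,
    make_vortex_phase_movie,
)


def brute_force_singularities(phase, dx):
    """Independent 4-point winding-number oracle (plain Python loops)."""

    def wrap(a):
        while a <= -np.pi:
            a += 2 * np.pi
        while a > np.pi:
            a -= 2 * np.pi
        return a

    ny, nx = phase.shape
    found = []
    for y in range(ny - 1):
        for x in range(nx - 1):
            corners = [
                phase[y, x], phase[y, x + 1], phase[y + 1, x + 1], phase[y + 1, x]
            ]
            if any(np.isnan(c) for c in corners):
                continue
            w = sum(
                wrap(corners[(i + 1) % 4] - corners[i]) for i in range(4)
            ) / (2 * np.pi)
            q = int(round(w))
            if q != 0:
                found.append(((x + 0.5) * dx, (y + 0.5) * dx, q))
    return found


# ---------------------------------------------------------------------------
# phase
# ---------------------------------------------------------------------------

def test_analytic_phase_of_sinusoid_advances_linearly():
    t = np.arange(0, 2000.0, 5.0)
    data = (-80 + 20 * np.sin(2 * np.pi * 6e-3 * t))[:, None, None] * np.ones(
        (1, 3, 3)
    )
    mv = VmMovie(data=data, dt=5.0, dx=0.5)
    ph = compute_phase(mv)
    rate = np.diff(np.unwrap(ph[:, 1, 1])).mean() / 5.0  # rad/ms
    assert rate * 1e3 / (2 * np.pi) == pytest.approx(6.0, rel=0.01)


def test_quiescent_voxel_phase_is_undefined():
    data = np.full((100, 2, 2), -80.0)
    data[:, 0, 0] += 10 * np.sin(np.linspace(0, 20, 100))
    ph = compute_phase(VmMovie(data=data, dt=5.0, dx=0.5))
    assert np.isnan(ph[:, 1, 1]).all()
    assert not np.isnan(ph[:, 0, 0]).any()


def test_embedding_phase_rotates_at_same_rate_as_analytic():
    t = np.arange(0, 3000.0, 5.0)
    data = (20 * np.sin(2 * np.pi * 5e-3 * t))[:, None, None] * np.ones((1, 2, 2))
    mv = VmMovie(data=data, dt=5.0, dx=0.5)
    ph_a = compute_phase(mv)
    ph_e = compute_phase_embedding(mv, delay_ms=50.0)  # quarter period
    ra = np.diff(np.unwrap(ph_a[:, 0, 0])).mean()
    re = np.diff(np.unwrap(ph_e[20:, 0, 0])).mean()
    assert ra == pytest.approx(re, rel=0.02)


# ---------------------------------------------------------------------------
# singularities
# ---------------------------------------------------------------------------

def test_ideal_vortex_detected_at_center_with_charge():
    ph, dtms, dx = make_vortex_phase_movie(
        center=(5.0, 5.0), chirality=1, frequency=5.0, duration=400.0
    )
    tracks = track_singularities(ph, dtms, dx)
    assert len(tracks) == 1
    tr = tracks[0]
    assert tr.charge == 1
    assert np.allclose(tr.x, 5.0, atol=dx) and np.allclose(tr.y, 5.0, atol=dx)
    ph2, _, _ = make_vortex_phase_movie(chirality=-1, duration=100.0)
    assert track_singularities(ph2, dtms, dx)[0].charge == -1


def test_uniform_phase_field_has_no_singularity():
    assert frame_singularities(np.zeros((20, 20)), 0.1) == []


def test_detector_equals_brute_force_oracle_on_synthetic_fields():
    """Vectorized plaquette winding agrees with the loop oracle on vortex
    frames and random smooth phase fields."""
    ph, _, dx = make_vortex_phase_movie(duration=50.0)
    rng = np.random.default_rng(11)
    frames = list(ph[:5])
    # smooth random fields: sums of a few vortex pairs
    n = 40
    xs = (np.arange(n) + 0.5) * 0.25
    gx, gy = np.meshgrid(xs, xs)
    for _ in range(5):
        f = np.zeros((n, n))
        for _ in range(3):
            cx, cy = rng.uniform(1, 9, 2)
            q = rng.choice([-1, 1])
            f = f + q * np.arctan2(gy - cy, gx - cx)
        frames.append((f + np.pi) % (2 * np.pi) - np.pi)
    for frame in frames:
        got = sorted(frame_singularities(frame, 0.25))
        want = sorted(brute_force_singularities(frame, 0.25))
        assert got == want


def test_opposite_vortex_pair_has_zero_net_charge():
    n = 60
    xs = (np.arange(n) + 0.5) * 0.2
    gx, gy = np.meshgrid(xs, xs)
    f = np.arctan2(gy - 4.0, gx - 3.0) - np.arctan2(gy - 8.0, gx - 9.0)
    f = (f + np.pi) % (2 * np.pi) - np.pi
    sings = frame_singularities(f, 0.2)
    assert len(sings) == 2
    assert sum(q for _, _, q in sings) == 0


def test_colliding_plane_waves_produce_no_singularity():
    a = make_plane_wave_movie(400.0, shape=(40, 40), dx=0.25, dt_sample=1.0,
                              direction=(1, 0))
    b = make_plane_wave_movie(400.0, shape=(40, 40), dx=0.25, dt_sample=1.0,
                              direction=(-1, 0))
    nt = min(a.data.shape[0], b.data.shape[0])
    merged = VmMovie(
        data=np.maximum(a.data[:nt], b.data[:nt]), dt=1.0, dx=0.25
    )
    ph = compute_phase(merged)
    tracks = track_singularities(ph, 1.0, 0.25)
    # no persistent phase defect anywhere
    assert all(tr.duration < 20.0 for tr in tracks)


# ---------------------------------------------------------------------------
# pseudo-ECG
# ---------------------------------------------------------------------------

def test_pseudo_ecg_zero_for_uniform_field():
    mv = VmMovie(data=np.full((40, 30, 30), -80.0), dt=1.0, dx=0.5)
    assert np.all(pseudo_ecg(mv).signal == 0.0)


def test_pseudo_ecg_symmetric_source_cancels():
    """A single active voxel equidistant from both electrodes produces a
    null difference signal."""
    n = 31
    data = np.full((40, n, n), -80.0, dtype=float)
    data[:, n // 2, n // 2] = -80.0 + 100 * np.sin(np.linspace(0, 6, 40))
    mv = VmMovie(data=data, dt=1.0, dx=0.5)
    ecg = pseudo_ecg(mv)
    assert np.max(np.abs(ecg.signal)) < 1e-9 * 100


def test_pseudo_ecg_antisymmetric_under_electrode_swap():
    mv = make_plane_wave_movie(500.0, shape=(50, 50), dx=0.5, dt_sample=1.0)
    e1 = pseudo_ecg(mv)
    e2 = pseudo_ecg(mv, electrodes=(e1.electrodes[1], e1.electrodes[0]))
    assert np.max(np.abs(e1.signal)) > 0
    np.testing.assert_allclose(e1.signal, -e2.signal, atol=1e-12)


def test_pseudo_ecg_rejects_electrode_in_tissue_plane():
    mv = VmMovie(data=np.zeros((5, 10, 10)), dt=1.0, dx=0.5)
    with pytest.raises(ValueError, match="tissue plane"):
        pseudo_ecg(mv, electrodes=((2.0, 2.0, 0.0), (4.0, 2.0, 5.0)))


# ---------------------------------------------------------------------------
# dominant frequency
# ---------------------------------------------------------------------------

def test_dominant_frequency_on_sinusoids():
    fs = 1000.0
    t = np.arange(0, 4.0, 1 / fs)
    assert dominant_frequency(np.sin(2 * np.pi * 6 * t), fs) == pytest.approx(
        6.0, abs=0.25
    )
    mixed = np.sin(2 * np.pi * 3 * t) + 2.0 * np.sin(2 * np.pi * 7 * t)
    assert dominant_frequency(mixed, fs) == pytest.approx(7.0, abs=0.25)


def test_dominant_frequency_rejects_flat_signal():
    with pytest.raises(ValueError, match="no oscillation"):
        dominant_frequency(np.zeros(1000), 1000.0)


def test_vortex_point_signal_df_matches_rotation_frequency():
    ph, dtms, dx = make_vortex_phase_movie(frequency=5.0, duration=2000.0)
    sig = np.cos(ph[:, 10, 30])
    assert dominant_frequency(sig, 1e3 / dtms) == pytest.approx(5.0, abs=0.15)
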