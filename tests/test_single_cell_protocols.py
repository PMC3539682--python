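"""Feature extraction, pacing bookkeeping, stability and alternans."""

import math

import numpy as np
import pytest

from atrialbench.cell_models import get_model
from atrialbench.single_cell_protocols import (
    Trace,
    beat_features,
    detect_alternans,
    extract_ap_features,
    long_term_stability,
    pace,
)


def _linear_ap_trace(dt=0.1, rest=-80.0, peak=20.0, fall_ms=200.0, lead=10.0):
    """Rest, instantaneous jump to peak at t=lead, linear return to rest."""
    t = np.arange(0.0, lead + fall_ms + 50.0, dt)
    v = np.full_like(t, rest)
    amp = peak - rest
    falling = (t >= lead) & (t <= lead + fall_ms)
    v[falling] = peak - amp * (t[falling] - lead) / fall_ms
    return Trace(t0=0.0, dt_sample=dt, v=v, cai=None,
                 stim_times=np.array([lead - 1.0]))


def test_features_of_linear_synthetic_ap():
    """Rest -80, jump to +20, linear 200 ms return: amplitude 100 mV,
    APD50 = 100 ms, APD90 = 180 ms by construction."""
    f = extract_ap_features(_linear_ap_trace(), 0)
    assert f.amplitude == pytest.approx(100.0, abs=0.5)
    assert f.rmp == pytest.approx(-80.0, abs=1e-9)
    assert f.apd50 == pytest.approx(100.0, abs=0.5)
    assert f.apd90 == pytest.approx(180.0, abs=0.5)


def test_constant_trace_is_rejected():
    tr = Trace(t0=0.0, dt_sample=0.1, v=np.full(1000, -80.0), cai=None,
               stim_times=np.array([10.0]))
    with pytest.raises(ValueError, match="no AP"):
        extract_ap_features(tr, 0)


def test_apd_undefined_when_repolarization_incomplete():
    """An AP cut off before reaching 90% repolarization yields NaN APD90."""
    tr = _linear_ap_trace(fall_ms=400.0)
    tr.v = tr.v[:3000]  # truncate at 300 ms: past 50% but short of 90%
    f = extract_ap_features(tr, 0)
    assert math.isnan(f.apd90)
    assert not math.isnan(f.apd50)


def test_pace_short_duration_delivers_single_stimulus(mock_cell_basic):
    mock = mock_cell_basic
    tr = pace(mock, bcl=1.0, duration=0.5, dt=0.02)
    assert len(tr.stim_times) == 1


def test_mock_cell_apd_stable_across_beats(mock_cell_basic):
    mock = mock_cell_basic
    tr = pace(mock, bcl=1.0, duration=4.0, dt=0.02)
    feats = beat_features(tr)
    for f in feats:
        assert f.apd90 == pytest.approx(150.0, abs=3.0)


def test_feature_extraction_sampling_rate_stable():
    """Halving the sample period changes APD90 by < 0.5 ms on a model
    trace."""
    m = get_model("courtemanche")
    a = extract_ap_features(pace(m, bcl=1.0, duration=2.0, dt_sample=0.1), -1)
    b = extract_ap_features(pace(m, bcl=1.0, duration=2.0, dt_sample=0.05), -1)
    assert abs(a.apd90 - b.apd90) < 0.5


def test_long_term_stability_quiescent_mock_is_flat(mock_cell_basic):
    mock = mock_cell_basic
    rec = long_term_stability(
        mock, paced_minutes=0.0, quiescent_minutes=0.05, dt=0.05
    )
    assert rec.quiescent_rmp.size >= 3
    assert np.ptp(rec.quiescent_rmp) < 1e-6
    assert rec.beat_times.size == 0


# ---------------------------------------------------------------------------
# alternans classification
# ---------------------------------------------------------------------------

def _brute_force_period(x):
    """Oracle: dominant periodicity by discrete periodogram of the
    mean-removed sequence (periods 2 and 3 only)."""
    x = np.asarray(x, float) - np.mean(x)
    n = len(x)
    power = {}
    for p, freq in ((2, 0.5), (3, 1.0 / 3.0)):
        c = np.sum(x * np.cos(2 * np.pi * freq * np.arange(n)))
        s = np.sum(x * np.sin(2 * np.pi * freq * np.arange(n)))
        power[p] = (c * c + s * s) / n
    return max(power, key=power.get)


@pytest.mark.parametrize(
    "seq,expected,amp",
    [
        ([100.0] * 8, "none", 0.0),
        ([120.0, 80.0] * 4, "period-2", 40.0),
        ([90.0, 90.0, 120.0] * 3, "period-3", None),
        ([100.0, 100.5, 99.6, 100.2] * 2, "none", 0.0),
    ],
)
def test_detect_alternans_on_constructed_sequences(seq, expected, amp):
    pattern, amplitude = detect_alternans(seq)
    assert pattern == expected
    if amp is not None:
        assert amplitude == pytest.approx(amp, abs=1e-9)
    if expected in ("period-2", "period-3"):
        assert _brute_force_period(seq) == int(expected[-1])


def test_detect_alternans_agrees_with_periodogram_oracle():
    rng = np.random.default_rng(7)
    for _ in range(20):
        period = rng.choice([2, 3])
        base = 150.0 + rng.normal(0, 0.3, size=12)
        pattern = np.zeros(12)
        mag = rng.uniform(8, 40)
        pattern[::period] = mag
        seq = base + pattern
        cls, _ = detect_alternans(seq)
        assert cls == f"period-{period}"
        assert _brute_force_period(seq) == period


def test_detect_alternans_needs_enough_beats():
    with pytest.raises(ValueError):
        detect_alternans([100.0] * 5)
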