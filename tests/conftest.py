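"""Shared fixtures.

The expensive simulations (50 s pacing runs, conductivity tuning, strand
protocols, the scaled rotor) are session-scoped so the unit and acceptance
tests share one computation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from atrialbench.cell_models import get_model
from atrialbench.monodomain_solver import (
    CAF_CONDUCTIVITY_FACTOR,
    find_tissue_threshold,
    prepace_state,
    strand_cv,
    tune_conductivity,
)
from atrialbench.restitution_1d import measure_erp, run_strand_protocol
from atrialbench.single_cell_protocols import extract_ap_features, pace

MODELS = ("courtemanche", "nygren", "maleckar")


@pytest.fixture(scope="session")
def mock_cell_basic():
    """Calibrated mock excitable cell (APD 150 ms), shared — construction
    simulates the pacing calibration loop once."""
    from atrialbench.synthetic_fixtures import make_mock_cell

    return make_mock_cell(rmp=-80.0, amplitude=100.0, apd=150.0)


@pytest.fixture(scope="session")
def mock_cell_refractory():
    """Mock cell with calibrated refractory period (APD 150 ms, ERP
    200 ms); the ERP calibration runs the strand protocol several times,
    so it is shared across every test that needs it."""
    from atrialbench.synthetic_fixtures import make_mock_cell

    return make_mock_cell(rmp=-80.0, amplitude=100.0, apd=150.0,
                          refractory=200.0)


@pytest.fixture(scope="session")
def terminal_features():
    """Terminal-beat AP/CaT features after 50 s pacing at BCL 1 s for every
    implemented model, control and chronic-AF."""
    out = {}
    for base in MODELS:
        for key in (base, base + "-caf"):
            trace = pace(get_model(key), bcl=1.0, duration=50.0)
            out[key] = extract_ap_features(trace, -1)
    return out


@pytest.fixture(scope="session")
def tuned_diffusivity():
    """Control-variant diffusivity tuned to CV ~750 mm/s at BCL 1 s."""
    return {base: tune_conductivity(get_model(base)) for base in MODELS}


@pytest.fixture(scope="session")
def strand04(tuned_diffusivity):
    """BCL 0.4 s strand protocol + ERP for control and cAF Courtemanche."""
    out = {}
    for key in ("courtemanche", "courtemanche-caf"):
        model = get_model(key)
        d = tuned_diffusivity["courtemanche"]
        if model.variant == "caf":
            d *= CAF_CONDUCTIVITY_FACTOR
        proto = run_strand_protocol(model, 0.4, diffusivity=d)
        erp = measure_erp(model, 0.4, proto)
        out[key] = {"proto": proto, "erp": erp}
    return out


@pytest.fixture(scope="session")
def convergence_cv(tuned_diffusivity):
    """Strand CV for each model at (dt, dx) combinations used by the
    numerical-convergence checks: (0.01, 0.1), (0.005, 0.1), (0.01, 0.2).
    The stimulus amplitude found at the reference resolution is reused so
    resolution is the only difference between runs."""
    out = {}
    for base in MODELS:
        model = get_model(base)
        d = tuned_diffusivity[base]
        s0 = prepace_state(model, 1.0)
        states = np.tile(s0, (200, 1))
        amp = 1.2 * find_tissue_threshold(model, states, d)
        out[base] = {
            (0.01, 0.1): strand_cv(model, d, 1.0, n_beats=1, dt=0.01,
                                   dx=0.1, stim_amp=amp),
            (0.005, 0.1): strand_cv(model, d, 1.0, n_beats=1, dt=0.005,
                                    dx=0.1, stim_amp=amp),
            (0.01, 0.2): strand_cv(model, d, 1.0, n_beats=1, dt=0.01,
                                   dx=0.2, stim_amp=amp),
        }
    return out


@pytest.fixture(scope="session")
def scaled_rotor(tuned_diffusivity):
    """Scaled-down chronic-AF Courtemanche rotor: 25 mm patch, dx 0.25 mm,
    diffusivity reduced to shrink the wavelength into the patch, one planar
    S1 then a cross-field S2.  Provides the movie and its singularity
    analysis for the 2D property checks."""
    from atrialbench.rotor_2d import s1s2_cross_field

    model = get_model("courtemanche-caf")
    diff = 0.018
    last = None
    for s2 in (170.0, 150.0, 190.0):
        out = s1s2_cross_field(
            model, diff, patch_mm=25.0, dx=0.25, bcl=0.4, n_s1=1,
            s2_offset_ms=s2, observe_ms=700.0, persist_ms=450.0,
            dt=0.02, sample_ms=5.0,
        )
        last = out
        if out.success:
            return out
    return last
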