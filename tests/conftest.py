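import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polfret import KineticScheme, PhotophysicsModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def noiseless_phys():
    """Deterministic photophysics: dual label only, no noise, no bleaching,
    no backgrounds or red-laser excess, so rendered E* equals the configured
    state value exactly."""
    return PhotophysicsModel(
        noise_sd=0.0,
        background_DD=0.0,
        background_DA=0.0,
        red_excess_DA=0.0,
        acceptor_bleach_rate=0.0,
        donor_bleach_rate=0.0,
        label_fractions={"dual": 1.0, "donor_only": 0.0, "acceptor_only": 0.0, "unlabelled": 0.0},
    )


@pytest.fixture
def clean_phys():
    """Realistic intensities/noise but dual-label only and no bleaching:
    used for recovery tests that target kinetics, not stoichiometry."""
    return PhotophysicsModel(
        acceptor_bleach_rate=0.0,
        donor_bleach_rate=0.0,
        label_fractions={"dual": 1.0, "donor_only": 0.0, "acceptor_only": 0.0, "unlabelled": 0.0},
    )


@pytest.fixture
def binary_scheme():
    """Binary-complex fingers dynamics on extensible DNA (no nucleotides)."""
    return KineticScheme(k_close=1.4, k_open=5.3, n_max=0, t_add=None)


def two_state_series(rng, n_frames, frame_dt, mean_lo, mean_hi, sd, k_up, k_down):
    """Discrete-time two-state E* series for HMM tests (independent of the
    package's own simulator)."""
    p_up = 1.0 - np.exp(-k_up * frame_dt)
    p_down = 1.0 - np.exp(-k_down * frame_dt)
    state = np.empty(n_frames, dtype=int)
    s = 0
    for t in range(n_frames):
        state[t] = s
        if s == 0 and rng.random() < p_up:
            s = 1
        elif s == 1 and rng.random() < p_down:
            s = 0
    levels = np.where(state == 1, mean_hi, mean_lo)
    return levels + rng.normal(0.0, sd, n_frames), state
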