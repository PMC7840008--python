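import numpy as np
import pytest

from cuelearn import CohortConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Outcome-only config: 2 subjects, 60 trials, no kinematics."""
    return CohortConfig(n_subjects=2, n_trials=60, include_kinematics=False, seed=11)


@pytest.fixture
def kin_config():
    """Tiny cohort with kinematics (1 subject, 30 trials)."""
    return CohortConfig(n_subjects=1, n_trials=30, seed=21)


@pytest.fixture
def kin_session(kin_config):
    return generate_session(0, kin_config)


def bump_window(n_samples=61, n_channels=4, amps=None, rng=None, noise=0.0, peak=30):
    """Deterministic velocity window: per-channel Gaussian bumps."""
    if amps is None:
        amps = np.linspace(1.0, 2.0, n_channels)
    t = np.arange(n_samples)
    bump = np.exp(-((t - peak) ** 2) / (2 * 8.0**2))
    win = bump[:, None] * np.asarray(amps)[None, :]
    if noise > 0:
        win = win + rng.normal(0, noise, win.shape)
    return win
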