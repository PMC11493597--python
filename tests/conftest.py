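"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from vgrf.config import CohortConfig, RunConfig
from vgrf.simulate import simulate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A noiseless 4-subject, 3-speed cohort with its ground-truth table."""
    config = CohortConfig(
        n_subjects=4,
        speeds=(2.22, 2.78, 3.33),
        trial_duration=15.0,
        noise_sd_accel=0.0,
        noise_sd_grf=0.0,
        seed=7,
    )
    trials, truth = simulate_cohort(config)
    return config, trials, truth


@pytest.fixture(scope="session")
def noiseless_run_config(noiseless_cohort):
    config, _, _ = noiseless_cohort
    return RunConfig(cohort=config, seed=7)


@pytest.fixture(scope="session")
def noisy_cohort():
    """A small cohort at the default (realistic) noise levels."""
    config = CohortConfig(
        n_subjects=6, speeds=(2.22, 2.78), trial_duration=12.0, seed=21
    )
    trials, truth = simulate_cohort(config)
    return config, trials, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
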