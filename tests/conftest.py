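"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pytest

from stepthrow.config import AnalysisConfig, GeneratorParams
from stepthrow.pipeline import analyze_cohort
from stepthrow.synth import simulate_cohort


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Two subjects x 32 trials at default noise (24 constant / 8 jump each)."""
    params = GeneratorParams(n_subjects=2, trials_per_subject=32, seed=42)
    trials, gt = simulate_cohort(params)
    return params, trials, gt


@pytest.fixture(scope="session")
def small_result(small_cohort, cfg):
    _, trials, _ = small_cohort
    return analyze_cohort(trials, cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """One subject x 32 trials with every noise source switched off."""
    params = GeneratorParams(n_subjects=1, trials_per_subject=32, seed=7,
                             noise_force_sd=0.0, noise_cop_sd=0.0,
                             noise_marker_sd=0.0, motor_noise_sd=0.0)
    trials, gt = simulate_cohort(params)
    return params, trials, gt
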