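"""Shared fixtures: tiny synthetic cohorts kept at smoke scale."""

from __future__ import annotations

import numpy as np
import pytest

from thetanet.simulate import SimulationConfig, build_cohort_generator, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimulationConfig:
    """Smallest cohort that still exercises every pipeline stage."""
    return SimulationConfig(
        n_per_group=2,
        n_channels=16,
        fs=128.0,
        rest_duration=16.0,
        n_trials=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def ground_truth(tiny_config):
    return build_cohort_generator(tiny_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
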