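import numpy as np
import pytest

from mlmed.design import DesignSpec
from mlmed.synth import SimConfig


@pytest.fixture
def small_design() -> DesignSpec:
    """One-run design (36 trials) for fast end-to-end tests."""
    return DesignSpec(reps_per_condition=6, n_runs=1, trials_per_run=36)


@pytest.fixture
def quiet_sim() -> SimConfig:
    """Low-noise simulation config for recovery tests."""
    return SimConfig(mediator_noise_sd=0.3, rating_noise_sd=0.3,
                     drift_amplitude=0.2, ar_innovation_sd=0.2,
                     motion_step_sd=0.01, motion_leak_amplitude=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
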