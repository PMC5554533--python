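import numpy as np
import pytest

from decaylearn import TaskConfig, generate_task


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_task():
    """The standard 4-cue / 4-outcome quasi-stochastic task."""
    return TaskConfig(seed=0)


@pytest.fixture
def default_sequence(default_task):
    return generate_task(default_task)


@pytest.fixture
def single_cue_sequence():
    """Single-cue continuous task with observation noise, 50 trials."""
    return generate_task(
        TaskConfig(
            n_cues=1,
            n_outcomes=1,
            outcome_type="continuous",
            violation_prob=0.0,
            continuous_noise_sd=0.3,
            n_trials=50,
            seed=11,
        )
    )
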