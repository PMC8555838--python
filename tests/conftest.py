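import numpy as np
import pytest

import signsynergy as ss


@pytest.fixture(scope="session")
def markerset():
    return ss.MarkerSet.default_upper_body()


@pytest.fixture(scope="session")
def small_config():
    """A cheap cohort: 3 signers x 4 trials x 2 s at 250 fps."""
    return ss.CohortConfig(n_signers=3, n_trials=4, trial_s=2.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Generated trials plus ground truth for the cheap cohort."""
    return ss.generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_normalized(small_cohort):
    trials, _truth = small_cohort
    return ss.normalized_cohort_from_trials(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _random_trial(rng, markerset, n_frames=40, frame_rate=250.0, signer="sA", trial="sA__t0"):
    frames = rng.normal(0.0, 100.0, size=(n_frames, markerset.count, 3))
    return ss.Trial(signer, trial, frames, frame_rate)


@pytest.fixture(scope="session")
def random_trial():
    """Factory fixture: random_trial(rng, markerset, ...) -> Trial."""
    return _random_trial
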