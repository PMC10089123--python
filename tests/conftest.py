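import numpy as np
import pytest

from micross import EpochSet, SyntheticConfig, generate_cohort, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_epochs(rng) -> EpochSet:
    """Unlabeled i.i.d. unit-variance noise trials, 4 channels."""
    return EpochSet(
        data=rng.standard_normal((20, 4, 500)),
        fs=250.0,
        channels=("A", "B", "C", "D"),
        subject_id="noise",
    )


@pytest.fixture
def labeled_epochs(rng) -> EpochSet:
    data = rng.standard_normal((16, 4, 250))
    labels = np.tile([1, -1], 8)
    return EpochSet(data=data, fs=250.0, channels=("A", "B", "C", "D"),
                    labels=labels, subject_id="lab")


@pytest.fixture(scope="session")
def default_subject() -> EpochSet:
    """One synthetic subject at default (strong-effect) settings."""
    return generate_subject(SyntheticConfig(seed=7), 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for harness tests: 4 subjects, 20 trials/class."""
    cfg = SyntheticConfig(seed=3, n_subjects=4, trials_per_class=20)
    return generate_cohort(cfg)
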