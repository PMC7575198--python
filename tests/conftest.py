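import numpy as np
import pytest

from painloop import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_sequence():
    """One subject, 3 sessions x 10 trials, balanced Bernoulli labels."""
    seqs = synthetic.generate_trial_sequences(
        n_subjects=1, n_sessions=3, n_trials=10, p_high=0.5, seed=7
    )
    return next(iter(seqs.values()))


@pytest.fixture
def study_sequence():
    """Study-sized single subject: 6 sessions x 30 trials."""
    seqs = synthetic.generate_trial_sequences(
        n_subjects=1, n_sessions=6, n_trials=30, p_high=0.5, seed=11
    )
    return next(iter(seqs.values()))


@pytest.fixture
def calibrated_model():
    return synthetic.calibrated_emission_model()
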