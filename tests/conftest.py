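import numpy as np
import pytest

import stochtone as st


@pytest.fixture(scope="session")
def exp1_scale():
    return st.exp1_scale()


@pytest.fixture(scope="session")
def eeg_scale():
    return st.eeg_scale()


@pytest.fixture(scope="session")
def exp1_small():
    """Reduced Experiment-1-style set: 3 trials per condition, 60 tones."""
    seqs = st.generate_experiment("exp1", seed=7, trials_per_condition=3)
    return seqs, st.sequences_to_manifest(seqs)


@pytest.fixture(scope="session")
def markov_small():
    """Reduced EEG-style Markov set: 3 trials per condition, 50 tones."""
    seqs = st.generate_experiment("eeg", seed=5, trials_per_condition=3)
    return seqs, st.sequences_to_manifest(seqs)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
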