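import numpy as np
import pytest

from tetrosleep import SynthConfig, extract_matrix, gen_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced six-class synthetic set small enough for fast selector tests."""
    config = SynthConfig(n_per_class=8, seed=7)
    epochs, labels = gen_dataset(config)
    return epochs, np.asarray(labels)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    epochs, labels = small_dataset
    return extract_matrix(epochs), labels
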