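import numpy as np
import pytest

from sosbind.sampling import LabeledDataset
from sosbind.simulate import ImbalanceSpec, gen_imbalanced, gen_toy_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_imbalanced():
    """20 minority vs 200 majority, 3-D, clearly separated."""
    return gen_imbalanced(ImbalanceSpec(n_min=20, n_maj=200, d=3, separation=3.0, seed=7))


@pytest.fixture
def tiny_dataset():
    features = np.array([[0.0, 0.0], [1.0, 1.0], [0.1, 0.0], [0.9, 1.0], [0.5, 0.4]])
    labels = np.array([1, -1, 1, -1, -1])
    return LabeledDataset(features=features, labels=labels)


@pytest.fixture
def toy_profile():
    return gen_toy_profile(30, [5, 17], shift=4.0, seed=11)


def random_labeled(rng, n_min, n_maj, d):
    features = rng.normal(size=(n_min + n_maj, d))
    labels = np.concatenate([np.ones(n_min, dtype=int), -np.ones(n_maj, dtype=int)])
    perm = rng.permutation(n_min + n_maj)
    return LabeledDataset(features=features[perm], labels=labels[perm])
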