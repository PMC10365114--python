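import pickle

import numpy as np
import pytest

from cfaug import models as md
from cfaug import toyworld as tw


def clone(model):
    """Deep copy of a model (classifier or generator) including its state."""
    return pickle.loads(pickle.dumps(model))


@pytest.fixture(scope="session")
def balanced_ds() -> tw.ToyDataset:
    """Small balanced, uncoupled cohort at 32 px (shared, read-only)."""
    return tw.sample_dataset(300, seed=11, size=32)


@pytest.fixture(scope="session")
def oracle(balanced_ds):
    return balanced_ds.oracle()


@pytest.fixture(scope="session")
def pretrained(balanced_ds) -> md.MLPClassifier:
    """Classifier pre-trained on the balanced cohort (shared, read-only;
    use clone() before mutating)."""
    return md.pretrain_classifier(balanced_ds, md.TrainConfig(epochs=12, seed=0))


@pytest.fixture(scope="session")
def neural_gen(balanced_ds, oracle) -> md.MLPGenerator:
    """Neural generator regressed onto the oracle (shared, read-only)."""
    cfg = md.TrainConfig(epochs=60, learning_rate=1e-3, seed=0,
                         n_pairs_per_sample=4)
    return md.train_neural_generator(balanced_ds, oracle, cfg, hidden=256)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
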