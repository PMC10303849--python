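import numpy as np
import pytest

from explainn.model import ModelConfig, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_onehot(n, length, seed=0):
    """(N, L, 4) one-hot batch of uniform random sequences."""
    gen = np.random.default_rng(seed)
    return np.eye(4)[gen.integers(0, 4, size=(n, length))].astype(float)


def random_sequences(n, length, seed=0):
    gen = np.random.default_rng(seed)
    lut = np.array(list("ACGT"))
    return ["".join(row) for row in lut[gen.integers(0, 4, size=(n, length))]]


@pytest.fixture()
def tiny_model():
    """A 3-unit model small enough for exhaustive checks."""
    cfg = ModelConfig(num_units=3, input_length=40, num_tasks=2, fc_hidden=8)
    return build_model(cfg, seed=7)
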