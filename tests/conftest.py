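import numpy as np
import pytest

from mscrepair import Dataset, SynthConfig, TrainConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """Five fully observed entries, three condition slots plus outcome."""
    rng = np.random.default_rng(7)
    values = rng.uniform(0.1, 0.9, size=(5, 4))
    return Dataset(values, np.ones((5, 4), dtype=bool),
                   ["x1", "x2", "x3", "repair_score"])


@pytest.fixture
def planted_noiseless():
    ds, truth = generate(SynthConfig(n=40, outcome="tanh", noise_sd=0.0, seed=1))
    return ds, truth


@pytest.fixture
def fast_cfg():
    """Small training schedule for structural (non-accuracy) tests."""
    return TrainConfig(hidden=2, walk_steps=30, descent_steps=30, seed=0)
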