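import numpy as np
import pytest

import eegnets as e


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def montage():
    return e.default_montage()


@pytest.fixture
def small_trials():
    """Fast default-structure trials: 4 per condition, 3 windows each."""
    cfg = e.SynthConfig(n_trials=4, epoch_s=0.45, seed=7)
    return e.generate_trials(cfg)


@pytest.fixture
def recording(rng):
    labels = list(e.default_montage().labels)
    data = rng.standard_normal((20, 780)) * 10.0
    return e.Recording(labels=labels, data=data, fs=600.0)


def random_adjacency(rng, n=20, p=0.2):
    """Random symmetric binary adjacency with zero diagonal."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return a + a.T
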