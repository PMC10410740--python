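import numpy as np
import pytest

from dopanet import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """A 2-5-neuron configuration whose every matrix is hand-enumerable."""
    return SimConfig(
        n_thal=2,
        n_ctx=4,
        ctx_exc_frac=0.5,
        n_dspn=2,
        n_ispn=2,
        d=2,
        n_trials=3,
        record_trials=1,
        snapshot_every=1,
        seed=7,
    )


@pytest.fixture
def desk_config():
    return SimConfig.desk(seed=3)


@pytest.fixture(scope="session")
def trained_desk_result():
    """One heterogeneous desk-profile training run, shared across tests."""
    from dopanet import BasalGangliaModel

    return BasalGangliaModel(SimConfig.desk(seed=42)).fit()
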