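import numpy as np
import pytest

from sandimri.protocol import connectome_protocol, group_shells
from sandimri.rf import PriorRanges, build_training_set, train_regressor


@pytest.fixture(scope="session")
def protocol():
    return connectome_protocol()


@pytest.fixture(scope="session")
def shells(protocol):
    return group_shells(protocol)


@pytest.fixture(scope="session")
def rf_model_clean():
    """Small forest trained on effectively noise-free forward simulations."""
    priors = PriorRanges()
    X, y = build_training_set(priors, sigma=1e-10, n_train=4000, seed=42)
    return train_regressor(X, y, n_trees=20, seed=42, priors=priors, sigma=1e-10)


@pytest.fixture(scope="session")
def rf_model_snr50():
    """Small forest trained at the in-vivo-like noise level sigma = 0.02."""
    priors = PriorRanges()
    X, y = build_training_set(priors, sigma=0.02, n_train=4000, seed=43)
    return train_regressor(X, y, n_trees=20, seed=43, priors=priors, sigma=0.02)
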