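import numpy as np
import pytest

from sgnc.affinity import PredictorConfig
from sgnc.synthetic import SyntheticSpec, make_codebook_fixture, make_latent_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale study conditions shared across tests."""
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def desk_dataset(desk_spec):
    return make_latent_dataset(desk_spec)


@pytest.fixture(scope="session")
def desk_fixture(desk_spec):
    return make_codebook_fixture(desk_spec)


@pytest.fixture
def fast_predictor_cfg():
    """Small architecture + hot learning rate: converges on linear data in seconds."""
    return PredictorConfig(
        hidden_sizes=(64, 128, 64),
        epochs=80,
        lr_schedule=[(60, 1e-3), (20, 1e-4)],
        seed=0,
    )
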