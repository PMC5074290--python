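import numpy as np
import pytest

from powderspec import (
    ShapeSpec,
    depolarization,
    from_oscillator_table,
    reference_models,
)


@pytest.fixture(scope="session")
def models():
    return reference_models()


@pytest.fixture(scope="session")
def mgo_model(models):
    return from_oscillator_table(models["mgo"], sigma=10.0)


@pytest.fixture(scope="session")
def sphere():
    return depolarization(ShapeSpec("sphere"))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
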