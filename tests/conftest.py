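import numpy as np
import pytest

from gahacr_sim import (
    ModelDefinition,
    VariantSpec,
    default_parameters,
)

#: Absolute slack for steady-state comparisons: 10x the residual tolerance.
SS_SLACK = 1e-7


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def gahacr_model(params):
    return ModelDefinition(params, VariantSpec("gahacr", "GA20ox"))


@pytest.fixture(scope="session")
def wildtype_model(params):
    return ModelDefinition(params, VariantSpec("wildtype", "none"))


@pytest.fixture(scope="session")
def no_degron_model(params):
    return ModelDefinition(params, VariantSpec("no_degron_cr", "GA20ox"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)


def random_states(rng, n, scale=2.0):
    """Non-negative random state vectors for property checks."""
    return rng.uniform(0.0, scale, size=(n, 17))
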