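import numpy as np
import pytest

from fermhybrid.datasets import (
    InitialConditionSpec,
    NoiseModel,
    draw_initial_conditions,
    generate_experiment,
)
from fermhybrid.kinetics import StateVector
from fermhybrid.params import GatingConfig, KineticParameters


@pytest.fixture(scope="session")
def params() -> KineticParameters:
    return KineticParameters.defaults()


@pytest.fixture(scope="session")
def gating() -> GatingConfig:
    return GatingConfig()


@pytest.fixture(scope="session")
def test_ic() -> StateVector:
    """The shifted-initial-condition validation run."""
    return draw_initial_conditions(InitialConditionSpec(), "test", 0)


@pytest.fixture(scope="session")
def train_mean_ic() -> StateVector:
    """Train-run nominal initial conditions (SDs zeroed)."""
    spec = InitialConditionSpec(
        train_sd={k: 0.0 for k in InitialConditionSpec().train_sd})
    return draw_initial_conditions(spec, "train", 0)


@pytest.fixture(scope="session")
def noiseless_test_ds(params, test_ic):
    """Noiseless test-role dataset on a fixed 25-point grid."""
    return generate_experiment(
        params, test_ic, noise=NoiseModel.noiseless(), rng_seed=7,
        role="test", times=np.linspace(0.0, 48.0, 25))


@pytest.fixture(scope="session")
def noisy_train_ds(params):
    """One noisy train-role dataset on the randomized sampling schedule."""
    ic = draw_initial_conditions(InitialConditionSpec(), "train", 11)
    return generate_experiment(params, ic, noise=NoiseModel(), rng_seed=11,
                               role="train")
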