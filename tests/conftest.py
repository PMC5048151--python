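import numpy as np
import pytest

from cryptax.datagen import (
    SpeciesModel,
    Scenario,
    default_scenario,
    gen_landmarks,
    gen_measurements,
    gen_sequences,
)
from cryptax.measurements import CHARACTERS

P = len(CHARACTERS)


def make_species(
    name="sp",
    mu=None,
    slope=None,
    size_sd=0.05,
    shape=None,
    diag=None,
    poly_rate=0.0,
    kappa=2.0,
):
    """Convenience builder with sensible small defaults."""
    if mu is None:
        mu = np.log(np.linspace(0.1, 0.5, P))
    if slope is None:
        slope = np.ones(P)
    if shape is None:
        shape = np.array(
            [[0, 0], [1, 0.2], [2, 0.3], [2.5, 0.1], [2, -0.1], [2.8, -0.5], [1, -0.8]],
            dtype=float,
        )
    return SpeciesModel(
        name=name,
        mu_log=mu,
        allometric_slope=slope,
        size_sd=size_sd,
        mean_shape=shape,
        diag_positions=diag or {},
        poly_rate=poly_rate,
        kappa=kappa,
    )


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=7, n_per_species=12)


@pytest.fixture(scope="session")
def measurements(scenario):
    return gen_measurements(scenario)


@pytest.fixture(scope="session")
def landmarks(scenario):
    return gen_landmarks(scenario, noise_sd=0.02)


@pytest.fixture(scope="session")
def sequences(scenario):
    return gen_sequences(scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
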