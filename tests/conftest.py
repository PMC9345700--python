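import numpy as np
import pytest

from cocontagion import ModelParameters, load_preset


@pytest.fixture(scope="session")
def reconciled():
    """Reference parameter preset with the recruitment rate at 5 persons/year."""
    return load_preset("table2_reconciled").params


@pytest.fixture(scope="session")
def printed():
    """Reference parameter preset exactly as tabulated (Lambda=50)."""
    return load_preset("table2_printed").params


@pytest.fixture(scope="session")
def persistence():
    """Super-threshold scenario parameters (beta1=0.001, beta2=0.004)."""
    return load_preset("fig5_persistence").params


@pytest.fixture(scope="session")
def eradication():
    """Sub-threshold scenario parameters (beta1=0.0001, beta2=0.0002)."""
    return load_preset("fig4_eradication").params


def random_parameters(rng: np.random.Generator) -> ModelParameters:
    """A random valid parameter set with epidemiologically plausible ranges."""
    return ModelParameters(
        Lambda=rng.uniform(0.5, 100.0),
        mu=rng.uniform(0.005, 0.5),
        beta1=rng.uniform(1e-5, 0.02),
        beta2=rng.uniform(1e-5, 0.02),
        beta_mod=rng.uniform(0.0, 2.0),
        kappa=rng.uniform(0.0, 2.0),
        delta=rng.uniform(0.05, 1.0),
        epsilon=rng.uniform(0.05, 1.0),
        alpha=rng.uniform(0.05, 1.0),
        sigma=rng.uniform(0.05, 1.0),
        rho=rng.uniform(0.05, 1.0),
        omega=rng.uniform(0.0, 1.0),
        phi=rng.uniform(0.05, 1.0),
        theta=rng.uniform(0.05, 1.0),
        theta1=rng.uniform(0.0, 2.0),
        theta2=rng.uniform(0.0, 2.0),
    )


def random_state(rng: np.random.Generator, n: int = 8) -> np.ndarray:
    """A random nonnegative compartment vector."""
    return rng.uniform(0.0, 500.0, size=n)
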