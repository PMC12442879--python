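import numpy as np
import pytest

from carbscape import ExperimentDesign, KineticParams, eq1_rate


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def toy_params():
    """A well-behaved inhibited optimum curve used across tests."""
    return KineticParams(X=1.5, Y=5.0, S=0.005)


@pytest.fixture(scope="session")
def clean_points(toy_params):
    """Noise-free (CO2, rate) points spanning the optimum curve."""
    c = np.linspace(0.5, 100.0, 12)
    return np.column_stack([c, eq1_rate(c, toy_params)])


@pytest.fixture(scope="session")
def noisy_points(toy_params):
    rng = np.random.default_rng(42)
    c = np.linspace(0.5, 100.0, 24)
    y = eq1_rate(c, toy_params) + rng.normal(0.0, 0.05, size=c.size)
    return np.column_stack([c, y])
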