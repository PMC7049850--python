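import numpy as np
import pytest

from tumor_immune import SolverConfig, outcome_matrix, patient1, patient2


@pytest.fixture(scope="session")
def p1():
    return patient1()


@pytest.fixture(scope="session")
def p2():
    return patient2()


@pytest.fixture(scope="session")
def scenario_matrix_default():
    """Outcome matrix for the full registry at the reference solver settings."""
    return outcome_matrix(config=SolverConfig(order=12, dt=2.0 ** -9))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
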