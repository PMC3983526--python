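import numpy as np
import pytest

import rbe2f as rb
from rbe2f.synth import Design, NoiseModel, generate


@pytest.fixture(scope="session")
def original():
    return rb.load_fixture("original")


@pytest.fixture(scope="session")
def opt1():
    return rb.load_fixture("opt1")


@pytest.fixture(scope="session")
def opt2():
    return rb.load_fixture("opt2")


@pytest.fixture(scope="session")
def opt3():
    return rb.load_fixture("opt3")


@pytest.fixture(scope="session")
def quiescent_original(original):
    return rb.quiescent_state(original)


@pytest.fixture(scope="session")
def zero_noise_dataset(original):
    """Noiseless 12-point dataset from the published parameter set."""
    return generate(original, design=Design(n_times=12),
                    noise=NoiseModel(sigma=0.0, seed=1))


@pytest.fixture(scope="session")
def original_branches(original):
    """Continuation branches and folds of the published set, S in [0, 2.5]."""
    return rb.model_folds(original)


def cubic_normal_form(r=3.0):
    """dx/dt = s + r*x - x^3: folds at s = -/+ 2*(r/3)**1.5 for r > 0."""
    def f(x, s):
        return np.array([s + r * x[0] - x[0] ** 3])

    def jac(x, s):
        return np.array([[r - 3.0 * x[0] ** 2]])

    return f, jac
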