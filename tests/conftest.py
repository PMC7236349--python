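import numpy as np
import pytest

from aamodel.models import SubstitutionModel
from aamodel.registry import get_model


def make_random_model(rng: np.random.Generator, name: str = "random") -> SubstitutionModel:
    """A valid random model: lognormal exchangeabilities, Dirichlet frequencies."""
    tri = rng.lognormal(mean=0.0, sigma=1.0, size=190)
    R = np.zeros((20, 20))
    rows, cols = np.tril_indices(20, -1)
    R[rows, cols] = tri
    R[cols, rows] = tri
    pi = rng.dirichlet(np.full(20, 5.0))
    return SubstitutionModel(name, R, pi)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def uniform_model():
    return SubstitutionModel(
        "uniform", np.ones((20, 20)) - np.eye(20), np.full(20, 0.05)
    )


@pytest.fixture
def mtort():
    return get_model("mtOrt")


@pytest.fixture
def lg():
    return get_model("LG")
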