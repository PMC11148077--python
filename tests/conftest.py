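import numpy as np
import pytest

from qmripls import noddi, phantom


@pytest.fixture(scope="session")
def scheme():
    return noddi.default_scheme()


@pytest.fixture(scope="session")
def small_truth():
    """A small phantom shared by read-only tests."""
    return phantom.make_phantom(phantom.PhantomSpec(n_subjects=30, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
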