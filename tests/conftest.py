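import numpy as np
import pytest

import lhnabm as L


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def ranges():
    return L.default_ranges()


@pytest.fixture(scope="session")
def default_scenario():
    return L.default_scenario()


@pytest.fixture
def tiny_scenario():
    """A small, fast cohort with the default mechanisms live."""
    s = L.default_scenario()
    return s.replace(n_care_centers=2, clinicians_per_center=2,
                     patients_per_clinician=5, horizon_steps=52, seed=7)


@pytest.fixture
def frozen_scenario():
    from lhnabm.io import make_fixture_scenario
    return make_fixture_scenario("frozen", seed=3)
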