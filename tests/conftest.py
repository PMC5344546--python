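import numpy as np
import pytest

from discfem import constitutive as con
from discfem import geometry as geo
from discfem import synthetic


@pytest.fixture(scope="session")
def materials():
    return con.OVINE_MATERIALS


@pytest.fixture(scope="session")
def fiber_pair():
    """Two unit fiber directions at +/-30 deg to x in the x-z plane."""
    a = np.radians(30.0)
    return np.array([[np.cos(a), 0.0, np.sin(a)],
                     [np.cos(a), 0.0, -np.sin(a)]])


@pytest.fixture(scope="session")
def single_element():
    return synthetic.make_fixture("single-element")


@pytest.fixture(scope="session")
def tension_bar():
    return synthetic.make_fixture("tension-bar")


@pytest.fixture(scope="session")
def mini_disc():
    return synthetic.make_fixture("mini-disc")


@pytest.fixture(scope="session")
def default_disc():
    return geo.build_disc_mesh(geo.DiscGeometryConfig())


@pytest.fixture(scope="session")
def mini_prestate(mini_disc, materials):
    """Swelling pre-stress on the mini disc, shared across FE tests."""
    from discfem.swelling import initialize_swelling
    return initialize_swelling(mini_disc, materials)


@pytest.fixture(scope="session")
def default_prestate(default_disc, materials):
    """Swelling pre-stress on the default coarse disc."""
    from discfem.swelling import initialize_swelling
    return initialize_swelling(default_disc, materials)
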