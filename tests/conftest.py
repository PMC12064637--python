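import numpy as np
import pytest

from osteoplan.mesh_core import canonicalize_case
from osteoplan.phantoms import PhantomSpec, make_phantom


def _case_for(phantom):
    return canonicalize_case(
        phantom.bone, phantom.tumor, phantom.access, phantom.n_planes, phantom.margin_mm
    )


@pytest.fixture(scope="session")
def corner_phantom():
    return make_phantom(PhantomSpec(kind="corner_column", resolution=10.0))


@pytest.fixture(scope="session")
def corner_case(corner_phantom):
    return _case_for(corner_phantom)


@pytest.fixture(scope="session")
def ellipsoid_phantom():
    return make_phantom(PhantomSpec(kind="eccentric_ellipsoid"))


@pytest.fixture(scope="session")
def ellipsoid_case(ellipsoid_phantom):
    return _case_for(ellipsoid_phantom)


@pytest.fixture(scope="session")
def bean_phantom():
    return make_phantom(PhantomSpec(kind="concave_bean"))


@pytest.fixture(scope="session")
def bean_case(bean_phantom):
    return _case_for(bean_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


# canonical-frame optimal corner-column path: tangent planes through the
# tumor faces at x = 10 and y = 10 (original frame), centroid at (2.5, 2.5)
CORNER_OPTIMAL_PATH = np.array([[7.5, -22.5], [7.5, 7.5], [-22.5, 7.5]])


@pytest.fixture(scope="session")
def corner_optimal_path():
    return CORNER_OPTIMAL_PATH.copy()
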