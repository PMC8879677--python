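import numpy as np
import pytest

from spineforge.phantoms import PhantomSpec, make_spine_phantom
from spineforge.projection import ProjectionGeometry


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom spec: 5 upper-thoracic vertebrae on a 32-voxel grid."""
    return PhantomSpec(n_vertebrae=5, grid_size=32, body_radius_range=(5.0, 8.0),
                       process_length_range=(6.0, 9.0), seed=0)


@pytest.fixture(scope="session")
def small_spine(small_spec):
    return make_spine_phantom(small_spec)


@pytest.fixture(scope="session")
def parallel_geometry() -> ProjectionGeometry:
    return ProjectionGeometry(mode="parallel")


@pytest.fixture(scope="session")
def perspective_geometry() -> ProjectionGeometry:
    return ProjectionGeometry()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
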