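import numpy as np
import pytest

from holoxylem.geometry import GeometryConfig
from holoxylem.phantom import PitSpec, build_pit_pair_phantom, build_tracheid_phantom


@pytest.fixture(scope="session")
def table_geometry():
    """The reference instrument configuration (full 900-angle schedule)."""
    return GeometryConfig()


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale schedule on the same optics: 36 angles, 5 deg step."""
    return GeometryConfig(n_projections=36, angle_step_deg=5.0)


@pytest.fixture(scope="session")
def pit_phantom():
    """Reference pit-pair phantom at the default 256^3 grid."""
    return build_pit_pair_phantom()


@pytest.fixture(scope="session")
def small_pit_phantom():
    """Half-dimension pit on a 128^3 grid (cheap tests)."""
    spec = PitSpec(
        chamber_diameter_nm=2115.0,
        membrane_thickness_nm=214.0,
        canal_slit_width_nm=526.0,
        canal_slit_breadth_nm=150.0,
        wall_thickness_nm=900.0,
        canal_depth_nm=450.0,
    )
    return build_pit_pair_phantom(spec, grid_shape=(128, 128, 128), pitch_nm=26.0)


@pytest.fixture(scope="session")
def tracheid_phantom():
    return build_tracheid_phantom()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
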