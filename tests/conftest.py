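import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from mavessel.membrane import PRESETS
from mavessel.meshes import ShapeSpec, build_cell_mesh


@pytest.fixture(scope="session")
def rbc500():
    """The full-resolution normal-RBC mesh (printed study parameters)."""
    params = PRESETS["rbc_normal"]()
    return build_cell_mesh(params.shape_spec, params.n_vertices), params


@pytest.fixture(scope="session")
def platelet48():
    params = PRESETS["platelet"]()
    return build_cell_mesh(params.shape_spec, params.n_vertices), params


@pytest.fixture(scope="session")
def rbc_coarse():
    """Coarse RBC mesh used by the desk-scale flow fixtures."""
    params = PRESETS["rbc_normal"]()
    return build_cell_mesh(params.shape_spec, 66), params


@pytest.fixture(scope="session")
def sphere_mesh():
    return build_cell_mesh(ShapeSpec("sphere", diameter=2.0), 162)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
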