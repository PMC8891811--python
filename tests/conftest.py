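import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import tfusim

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return tfusim.load_config()


@pytest.fixture(scope="session")
def small_config(default_config):
    """Coarse miniature domain for cheap algebraic solver checks."""
    grid = dataclasses.replace(
        default_config.grid, spacing=1.5e-4, radial_extent=0.012,
        axial_extent=0.030,
    )
    transducer = dataclasses.replace(
        default_config.transducer, curvature_radius=0.020,
        aperture_diameter=0.012,
    )
    return dataclasses.replace(
        default_config, grid=grid, transducer=transducer, standoff=0.004,
    )


@pytest.fixture(scope="session")
def column_config(default_config):
    """Narrow radially uniform column for quasi-1-D verification."""
    grid = dataclasses.replace(
        default_config.grid, spacing=5.0e-5, radial_extent=6.0e-4,
        axial_extent=0.040,
    )
    return dataclasses.replace(default_config, grid=grid, standoff=0.008)


@pytest.fixture(scope="session")
def water_solution(default_config):
    """Free-water reference field and focal peak at default settings."""
    return tfusim.water_baseline(default_config)


@pytest.fixture(scope="session")
def sweep_result():
    """Default skull-thickness sweep (2.0-9.0 mm) with its fitted law."""
    return tfusim.run_thickness_sweep()


@pytest.fixture(scope="session")
def multilayer_result():
    return tfusim.run_multilayer()
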