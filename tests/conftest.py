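import pytest
from hypothesis import settings

from lvaging import (
    DriverSet,
    GrowthLawParams,
    MaterialParams,
    SaturatingExponential,
    SimulationConfig,
    simulate,
)
from lvaging.presets import c57bl6_config

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    """Reference study conditions: aging C57BL/6J mice, 3-hour Euler step."""
    return c57bl6_config()


@pytest.fixture(scope="session")
def materials() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def drivers(config) -> DriverSet:
    return config.drivers


@pytest.fixture(scope="session")
def trajectory(config):
    """The full reference trajectory, simulated once per session."""
    return simulate(config)


@pytest.fixture(scope="session")
def coarse_config(config) -> SimulationConfig:
    """Reference conditions on a 24-hour step, for tests that run many
    simulations; endpoint shifts from the coarser step are < 0.01%."""
    return config.replace(step_hours=24.0)


@pytest.fixture()
def static_config() -> SimulationConfig:
    """Degenerate control: constant masses, zero pressure, so b = 0,
    lambda = 1 and the geometry must stay frozen."""
    zero = SaturatingExponential(0.0, 0.0, 0.0, 1.0)
    return SimulationConfig(
        drivers=DriverSet(
            total_mass=SaturatingExponential(76.88, 0.0, 8.18, 6.08),
            collagen_mass=SaturatingExponential(1.21, 0.0, 7.5, 7.23),
            pressure=zero,
        ),
        materials=MaterialParams(),
        growth=GrowthLawParams(),
        t_start=7.5,
        t_end=9.0,
        step_hours=24.0,
        R_i0=2.0,
        R_o0=2.92,
    )
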