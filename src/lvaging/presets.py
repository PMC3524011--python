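"""Reference study conditions: aging C57BL/6J wild-type mice.

Driver coefficients were fitted to necropsy, histology, and literature
pressure data for ~148 wild-type C57BL/6J mice aged 7.3-34 months; the
simulation window 7.5-30 months spans young to senescent animals.  These
values are the published study conditions, not tunables.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .drivers import DriverSet, MaterialParams, SaturatingExponential
from .growth import GrowthLawParams, SimulationConfig

__all__ = ["c57bl6_drivers", "c57bl6_config", "c57bl6_config_path"]


def c57bl6_drivers() -> DriverSet:
    """Fitted temporal drivers for aging C57BL/6J mice.

    Total LV mass 76.88 + 8.92(1 - exp(-(t-8.18)/6.08)) mg; collagen mass
    1.21 + 1.50(1 - exp(-(t-7.50)/7.23)) mg; transmural pressure
    4.5 + 3.0(1 - exp(-(t-2.5)/14.0)) mmHg, t in months.
    """
    return DriverSet(
        total_mass=SaturatingExponential(76.88, 8.92, 8.18, 6.08),
        collagen_mass=SaturatingExponential(1.21, 1.50, 7.50, 7.23),
        pressure=SaturatingExponential(4.5, 3.0, 2.5, 14.0),
    )


def c57bl6_config() -> SimulationConfig:
    """Full reference configuration: window 7.5-30 months, 3-hour Euler
    step, initial free radii R_i0 = 2.0 mm and R_o0 = 2.92 mm, and the
    calibrated growth law (tau_R = 0.22 mon, D = 2.5, tau_f = 5.6 mon).
    """
    return SimulationConfig(
        drivers=c57bl6_drivers(),
        materials=MaterialParams(),
        growth=GrowthLawParams(tau_R=0.22, D=2.5, tau_f=5.6),
        t_start=7.5,
        t_end=30.0,
        step_hours=3.0,
        R_i0=2.0,
        R_o0=2.92,
    )


def c57bl6_config_path() -> Path:
    """Path to the bundled YAML copy of the reference configuration."""
    return Path(str(resources.files("lvaging").joinpath("data/c57bl6.yaml")))
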