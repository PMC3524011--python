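"""Configuration and results I/O.

Configs are YAML (JSON is valid YAML and therefore also accepted) with an
explicit, schema-validated layout — every material constant and driver
coefficient is spelled out; the only defaulted field is
``hours_per_month``.  Trajectories are written as plain CSV with a fixed
column order so that downstream summaries recomputed from the file equal
the in-memory ones.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .analysis import SummaryReport
from .drivers import DriverSet, MaterialParams, SaturatingExponential
from .growth import (
    HOURS_PER_MONTH,
    GrowthLawParams,
    SimulationConfig,
    TRAJECTORY_COLUMNS,
    WallState,
    trajectory_frame,
)

__all__ = [
    "ConfigError",
    "read_config",
    "config_from_dict",
    "config_to_dict",
    "write_config",
    "write_trajectory",
    "read_trajectory",
    "write_summary",
]


class ConfigError(ValueError):
    """A configuration file violates the schema; names the offending field."""


_DRIVER_FIELDS = ("base", "amplitude", "onset_months", "tau_months")
_MATERIAL_FIELDS = ("rho_collagen", "rho_muscle", "E_collagen", "E_muscle", "poisson")
_GROWTH_FIELDS = ("tau_R", "D", "tau_f")
_SIM_REQUIRED = ("t_start", "t_end", "step_hours", "R_i0", "R_o0")


def _require(mapping: Mapping, key: str, where: str) -> object:
    if not isinstance(mapping, Mapping):
        raise ConfigError(f"section '{where}' must be a mapping")
    if key not in mapping:
        raise ConfigError(f"missing required field '{where}.{key}'" if where else
                          f"missing required field '{key}'")
    return mapping[key]


def _number(mapping: Mapping, key: str, where: str) -> float:
    value = _require(mapping, key, where)
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"field '{where}.{key}' must be a number, got {value!r}") from exc


def _driver(section: Mapping, where: str) -> SaturatingExponential:
    kwargs = {f: _number(section, f, where) for f in _DRIVER_FIELDS}
    try:
        return SaturatingExponential(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"invalid driver '{where}': {exc}") from exc


def config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a nested mapping."""
    drivers_sec = _require(data, "drivers", "")
    drivers = DriverSet(
        total_mass=_driver(_require(drivers_sec, "total_mass", "drivers"), "drivers.total_mass"),
        collagen_mass=_driver(
            _require(drivers_sec, "collagen_mass", "drivers"), "drivers.collagen_mass"
        ),
        pressure=_driver(_require(drivers_sec, "pressure", "drivers"), "drivers.pressure"),
    )
    mat_sec = _require(data, "materials", "")
    try:
        materials = MaterialParams(
            **{f: _number(mat_sec, f, "materials") for f in _MATERIAL_FIELDS}
        )
    except ValueError as exc:
        raise ConfigError(f"invalid materials: {exc}") from exc
    growth_sec = _require(data, "growth", "")
    try:
        growth = GrowthLawParams(**{f: _number(growth_sec, f, "growth") for f in _GROWTH_FIELDS})
    except ValueError as exc:
        raise ConfigError(f"invalid growth parameters: {exc}") from exc
    sim_sec = _require(data, "simulation", "")
    sim_kwargs = {f: _number(sim_sec, f, "simulation") for f in _SIM_REQUIRED}
    hours = (
        _number(sim_sec, "hours_per_month", "simulation")
        if "hours_per_month" in sim_sec
        else HOURS_PER_MONTH
    )
    try:
        return SimulationConfig(
            drivers=drivers,
            materials=materials,
            growth=growth,
            hours_per_month=hours,
            **sim_kwargs,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid simulation section: {exc}") from exc


def read_config(path: str | Path) -> SimulationConfig:
    """Read a YAML (or JSON) configuration file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def _driver_dict(f: SaturatingExponential) -> dict:
    return {
        "base": f.base,
        "amplitude": f.amplitude,
        "onset_months": f.onset_months,
        "tau_months": f.tau_months,
    }


def config_to_dict(config: SimulationConfig) -> dict:
    """Inverse of :func:`config_from_dict` on the schema."""
    return {
        "drivers": {
            "total_mass": _driver_dict(config.drivers.total_mass),
            "collagen_mass": _driver_dict(config.drivers.collagen_mass),
            "pressure": _driver_dict(config.drivers.pressure),
        },
        "materials": {f: getattr(config.materials, f) for f in _MATERIAL_FIELDS},
        "growth": {f: getattr(config.growth, f) for f in _GROWTH_FIELDS},
        "simulation": {
            "t_start": config.t_start,
            "t_end": config.t_end,
            "step_hours": config.step_hours,
            "R_i0": config.R_i0,
            "R_o0": config.R_o0,
            "hours_per_month": config.hours_per_month,
        },
    }


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def write_trajectory(trajectory: Sequence[WallState] | pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory as CSV with the canonical column order."""
    frame = (
        trajectory
        if isinstance(trajectory, pd.DataFrame)
        else trajectory_frame(trajectory)
    )
    frame.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"trajectory file missing columns: {missing}")
    return frame


def write_summary(report: SummaryReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
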