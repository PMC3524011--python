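"""Model/Results facade over the aging simulator.

:class:`LVAgingModel` bundles a :class:`~lvaging.growth.SimulationConfig`
(drivers, materials, geometry, time grid) and exposes simulation,
admissibility checking, and endpoint calibration; ``fit`` returns an
:class:`LVAgingResults` carrying the estimated growth-law parameters, the
grid resolution to which they are localized, diagnostics, and a
``summary()`` table.  Simulation at given (or fitted) parameters, the
EDPVR, the growth-rate bounds, and plots all hang off these two objects.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .analysis import SummaryReport, edpvr, summarize
from .calibration import CalibrationResult, CalibrationSpec, calibrate
from .config_io import config_from_dict, read_config
from .growth import (
    AdmissibilityReport,
    GrowthLawParams,
    SimulationConfig,
    WallState,
    bounds_frame,
    check_growth_function,
    growth_rate_bounds,
    simulate,
    trajectory_frame,
)

__all__ = ["LVAgingModel", "LVAgingResults"]


class LVAgingModel:
    """Life-span model of LV geometric remodeling in aging mice.

    Parameters
    ----------
    config : SimulationConfig
        The study conditions: temporal drivers, wall material, growth-law
        parameters, time window/step, and initial free radii.

    Examples
    --------
    >>> from lvaging import LVAgingModel
    >>> from lvaging.presets import c57bl6_config
    >>> model = LVAgingModel(c57bl6_config())
    >>> traj = model.simulate()
    >>> round(traj[-1].R_i, 3)
    2.043
    """

    def __init__(self, config: SimulationConfig):
        self.config = config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LVAgingModel":
        """Build from a YAML/JSON configuration file."""
        return cls(read_config(path))

    @classmethod
    def from_dict(cls, data: Mapping) -> "LVAgingModel":
        """Build from a nested configuration mapping."""
        return cls(config_from_dict(data))

    def simulate(self, growth: GrowthLawParams | None = None) -> list[WallState]:
        """Integrate one aging trajectory (optionally overriding the growth law)."""
        config = self.config if growth is None else self.config.replace(growth=growth)
        return simulate(config)

    def simulate_frame(self, growth: GrowthLawParams | None = None) -> pd.DataFrame:
        return trajectory_frame(self.simulate(growth))

    def check(self, trajectory: Sequence[WallState] | None = None) -> AdmissibilityReport:
        """Admissibility report for the configured growth law."""
        return check_growth_function(self.config, trajectory)

    def fit(self, targets: CalibrationSpec) -> "LVAgingResults":
        """Calibrate (tau_R, D, tau_f) to senescent-age endpoint targets."""
        result = calibrate(targets, self.config)
        return LVAgingResults(self, result, targets)


class LVAgingResults:
    """Calibrated growth-law parameters and everything derived from them."""

    def __init__(
        self, model: LVAgingModel, calibration: CalibrationResult, targets: CalibrationSpec
    ):
        self.model = model
        self.calibration = calibration
        self.targets = targets
        self._trajectory: list[WallState] | None = None

    @property
    def params(self) -> GrowthLawParams:
        return self.calibration.params

    @property
    def objective_mm2(self) -> float:
        return self.calibration.objective_mm2

    @property
    def config(self) -> SimulationConfig:
        """The model config with the fitted growth law substituted."""
        return self.model.config.replace(growth=self.params)

    @property
    def trajectory(self) -> list[WallState]:
        if self._trajectory is None:
            self._trajectory = simulate(self.config)
        return self._trajectory

    def summary_report(self) -> SummaryReport:
        return summarize(self.trajectory, self.config)

    def edpvr(self) -> pd.DataFrame:
        return edpvr(self.trajectory)

    def bounds(self) -> pd.DataFrame:
        return bounds_frame(growth_rate_bounds(self.trajectory, self.config))

    def check(self) -> AdmissibilityReport:
        return check_growth_function(self.config, self.trajectory)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cal = self.calibration
        last = self.trajectory[-1]
        rows = [
            ("tau_R (months)", f"{cal.params.tau_R:.4g}", f"+/- {cal.resolution[0]:.2g}"),
            ("D", f"{cal.params.D:.4g}", f"+/- {cal.resolution[1]:.2g}"),
            ("tau_f (months)", f"{cal.params.tau_f:.4g}", f"+/- {cal.resolution[2]:.2g}"),
        ]
        lines = [
            "Stretch-induced LV growth law — endpoint calibration",
            "=" * 56,
            f"{'parameter':<18}{'estimate':>12}{'grid res.':>14}",
            "-" * 56,
        ]
        lines += [f"{n:<18}{v:>12}{u:>14}" for n, v, u in rows]
        lines += [
            "-" * 56,
            f"objective (mm^2):        {cal.objective_mm2:.3e}",
            f"candidates evaluated:    {cal.n_evaluated}",
            f"R_i(t_end) achieved:     {last.R_i:.4f} mm "
            f"(target {self.targets.target_inner_radius_mm:.4f})",
            f"thickness(t_end):        {last.thickness:.4f} mm "
            f"(target {self.targets.target_wall_thickness_mm:.4f})",
            f"admissible:              {self.check().admissible}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p = self.params
        return (
            f"<LVAgingResults tau_R={p.tau_R:.4g} D={p.D:.4g} "
            f"tau_f={p.tau_f:.4g} objective={self.objective_mm2:.3e} mm^2>"
        )
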