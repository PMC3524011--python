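"""Endpoint calibration of the growth-law parameters.

The three growth-law parameters (tau_R, D, tau_f) are chosen to match two
senescent-age measurements: the free inner radius and the free wall
thickness at the end of the window.  The objective is the plain sum of
squared endpoint deviations,

    (R_i(t_end) - R_i,target)^2 + (WT(t_end) - WT_target)^2   [mm^2],

minimized by a deterministic coarse-to-fine grid search (no randomness,
no gradients — the objective is cheap, smooth, and three-dimensional).
Candidate parameter sets must be *admissible*: the simulation completes
and the outer radius, the wall thickness, and the net inner-radius change
all keep their non-decreasing aging trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth import (
    GrowthLawParams,
    GrowthSimulationError,
    SimulationConfig,
    check_growth_function,
    simulate,
)

__all__ = ["CalibrationSpec", "CalibrationResult", "calibrate"]


@dataclass(frozen=True)
class CalibrationSpec:
    """Targets and search ranges for the endpoint calibration.

    Ranges are inclusive (lo, hi) pairs; a degenerate range (lo == hi)
    pins that parameter.  ``grid_points`` per dimension and ``refinements``
    rounds of shrink-and-recenter control the search resolution.
    """

    target_inner_radius_mm: float
    target_wall_thickness_mm: float
    tau_R_range: tuple[float, float] = (0.05, 1.0)
    D_range: tuple[float, float] = (1.0, 4.0)
    tau_f_range: tuple[float, float] = (2.0, 10.0)
    grid_points: int = 5
    refinements: int = 3

    def __post_init__(self) -> None:
        if not self.target_inner_radius_mm > 0:
            raise ValueError("target inner radius must be > 0")
        if not self.target_wall_thickness_mm > 0:
            raise ValueError("target wall thickness must be > 0")
        for name in ("tau_R_range", "D_range", "tau_f_range"):
            lo, hi = getattr(self, name)
            if not (lo > 0 and hi >= lo):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.grid_points < 1 or self.refinements < 1:
            raise ValueError("grid_points and refinements must be >= 1")


@dataclass(frozen=True)
class CalibrationResult:
    """Best admissible parameter set and the achieved objective."""

    params: GrowthLawParams
    objective_mm2: float
    inner_radius_mm: float
    wall_thickness_mm: float
    n_evaluated: int
    #: Half-width of the final grid cell per parameter — the resolution to
    #: which the optimum is localized.
    resolution: tuple[float, float, float]


def _objective(
    params: GrowthLawParams, config: SimulationConfig, spec: CalibrationSpec
) -> tuple[float, float, float] | None:
    """Objective for one candidate; None if inadmissible."""
    candidate = config.replace(growth=params)
    try:
        trajectory = simulate(candidate)
    except GrowthSimulationError:
        return None
    report = check_growth_function(candidate, trajectory)
    if not report.admissible:
        return None
    last = trajectory[-1]
    obj = (last.R_i - spec.target_inner_radius_mm) ** 2 + (
        last.thickness - spec.target_wall_thickness_mm
    ) ** 2
    return obj, last.R_i, last.thickness


def _axis(lo: float, hi: float, n: int) -> np.ndarray:
    if hi == lo:
        return np.array([lo])
    return np.linspace(lo, hi, n)


def calibrate(spec: CalibrationSpec, config: SimulationConfig) -> CalibrationResult:
    """Deterministic coarse-to-fine grid search over (tau_R, D, tau_f).

    Each refinement round evaluates the full grid, then shrinks every
    range to one coarse cell around the incumbent (clipped to the original
    bounds).  Raises ``RuntimeError`` if no admissible point exists in the
    search region.
    """
    ranges = [spec.tau_R_range, spec.D_range, spec.tau_f_range]
    best: tuple[float, GrowthLawParams, float, float] | None = None
    n_eval = 0
    for _ in range(spec.refinements):
        axes = [_axis(lo, hi, spec.grid_points) for lo, hi in ranges]
        for tau_R in axes[0]:
            for D in axes[1]:
                for tau_f in axes[2]:
                    params = GrowthLawParams(tau_R=float(tau_R), D=float(D), tau_f=float(tau_f))
                    n_eval += 1
                    res = _objective(params, config, spec)
                    if res is None:
                        continue
                    obj, ri, wt = res
                    if best is None or obj < best[0]:
                        best = (obj, params, ri, wt)
        if best is None:
            raise RuntimeError(
                "no admissible growth-law parameters in the search ranges"
            )
        # shrink each non-degenerate range to +/- one coarse cell
        center = (best[1].tau_R, best[1].D, best[1].tau_f)
        new_ranges = []
        for (lo, hi), c, ax in zip(ranges, center, axes):
            if len(ax) == 1:
                new_ranges.append((lo, hi))
                continue
            cell = (hi - lo) / (len(ax) - 1)
            new_ranges.append((max(lo, c - cell), min(hi, c + cell)))
        ranges = new_ranges

    obj, params, ri, wt = best
    resolution = tuple(
        (hi - lo) / max(1, spec.grid_points - 1) / 2.0 for lo, hi in ranges
    )
    return CalibrationResult(
        params=params,
        objective_mm2=obj,
        inner_radius_mm=ri,
        wall_thickness_mm=wt,
        n_evaluated=n_eval,
        resolution=resolution,  # type: ignore[arg-type]
    )
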