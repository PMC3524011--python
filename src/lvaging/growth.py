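"""Stretch-induced growth of the LV shell over the life span.

The free outer radius grows at a rate set by the elastic stretch of the
outer surface, with an exponentially decaying remodeling intensity:

    d(alpha)/dt = f(t) = (lambda^D - 1) / tau_R * exp(-(t - t0)/tau_f),

where alpha(t) = R_o(t)/R_o(t0) and lambda(t) = r_o(t)/R_o(t) > 1 under
positive transmural pressure.  The free inner radius then follows from
conservation of wall tissue mass,

    R_o^2 dR_o/dt - R_i^2 dR_i/dt = b(t),

with b(t) the volumetric mass-flux term supplied by the fitted mass
drivers.  The coupled system is integrated with explicit first-order
Euler steps (default 3-hour step over 7.5-30 months); at every accepted
step the deformed radii are recovered from the thick-wall solution and
exact incompressibility.

The module also evaluates the admissibility bounds on f(t) that guarantee
non-decreasing inner radius (lower bound) and non-decreasing wall
thickness (upper bound), in both their trajectory-dependent ("tight") and
trajectory-free ("universal") forms, and produces a report of any
violations along a simulated trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .drivers import (
    MMHG_TO_PA,
    DriverSet,
    MaterialParams,
    collagen_fraction_at,
    composite_modulus,
    pressure_pa,
    volume_flux_b,
)
from .thickwall import (
    InadmissibleGeometryError,
    WallGeometry,
    deformed_thickness,
    mean_radial_stress,
    mean_tangential_stress,
    solve_deformed_radii,
)

__all__ = [
    "GrowthLawParams",
    "SimulationConfig",
    "WallState",
    "BoundsResult",
    "AdmissibilityReport",
    "GrowthSimulationError",
    "growth_rate",
    "euler_step",
    "simulate",
    "trajectory_frame",
    "max_outer_radius",
    "growth_rate_bounds",
    "check_growth_function",
    "TRAJECTORY_COLUMNS",
]

#: Default hours per month: 365.25/12 days of 24 h.
HOURS_PER_MONTH = 730.5

TRAJECTORY_COLUMNS = [
    "t_months",
    "R_i_mm",
    "R_o_mm",
    "r_i_mm",
    "r_o_mm",
    "alpha",
    "lambda",
    "v_c",
    "E_Pa",
    "P_mmHg",
    "P_Pa",
    "mean_sigma_rr_Pa",
    "mean_sigma_tt_Pa",
    "EDV_mm3",
]


class GrowthSimulationError(RuntimeError):
    """An Euler step produced an unphysical wall configuration."""

    def __init__(self, message: str, step: int | None = None, t: float | None = None):
        if step is not None:
            message = f"step {step} (t={t:.4f} months): {message}"
        super().__init__(message)
        self.step = step
        self.t = t


@dataclass(frozen=True)
class GrowthLawParams:
    """Parameters of the stretch-induced growth kernel.

    tau_R : remodeling characteristic time (months); smaller is faster.
    D     : stretch exponent on lambda (dimensionless).
    tau_f : decay constant (months) bounding the total amount of growth.
    """

    tau_R: float = 0.22
    D: float = 2.5
    tau_f: float = 5.6

    def __post_init__(self) -> None:
        for name in ("tau_R", "D", "tau_f"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one aging trajectory.

    Times in months, radii in mm; ``step_hours`` is converted to months
    through ``hours_per_month`` (defaults to the mean Julian month).
    """

    drivers: DriverSet
    materials: MaterialParams
    growth: GrowthLawParams
    t_start: float = 7.5
    t_end: float = 30.0
    step_hours: float = 3.0
    R_i0: float = 2.0
    R_o0: float = 2.92
    hours_per_month: float = HOURS_PER_MONTH

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")
        if not self.step_hours > 0:
            raise ValueError("step_hours must be > 0")
        if not self.hours_per_month > 0:
            raise ValueError("hours_per_month must be > 0")
        if not 0.0 < self.R_i0 < self.R_o0:
            raise ValueError(f"need 0 < R_i0 < R_o0, got ({self.R_i0}, {self.R_o0})")

    @property
    def step_months(self) -> float:
        return self.step_hours / self.hours_per_month

    @property
    def n_steps(self) -> int:
        return max(1, round((self.t_end - self.t_start) / self.step_months))

    def replace(self, **kwargs) -> "SimulationConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class WallState:
    """One time point of the trajectory with all derived quantities."""

    t: float
    R_i: float
    R_o: float
    r_i: float
    r_o: float
    alpha: float
    lam: float
    v_c: float
    E: float
    P: float  # Pa
    mean_sigma_rr: float
    mean_sigma_tt: float
    EDV: float

    @property
    def P_mmHg(self) -> float:
        return self.P / MMHG_TO_PA

    @property
    def thickness(self) -> float:
        return self.R_o - self.R_i


def growth_rate(lam: float, t: float, t0: float, gp: GrowthLawParams) -> float:
    """Growth rate f = (lambda^D - 1) exp(-(t - t0)/tau_f) / tau_R (1/month)."""
    if not lam > 0:
        raise ValueError(f"stretch ratio must be > 0, got {lam}")
    return (lam**gp.D - 1.0) / gp.tau_R * math.exp(-(t - t0) / gp.tau_f)


def _derived_state(
    t: float,
    R_i: float,
    R_o: float,
    alpha: float,
    config: SimulationConfig,
    step: int | None = None,
) -> WallState:
    """Assemble a WallState: deformed radii via the thick-wall solution."""
    drivers, mat = config.drivers, config.materials
    v_c = collagen_fraction_at(drivers, mat, t)
    E = composite_modulus(v_c, mat)
    P = pressure_pa(drivers, t)
    geom = WallGeometry(R_i=R_i, R_o=R_o)
    try:
        c = deformed_thickness(geom, P, E, mat.poisson)
        deformed = solve_deformed_radii(c, geom.cubic_gap)
    except InadmissibleGeometryError as exc:
        raise GrowthSimulationError(str(exc), step=step, t=t) from exc
    return WallState(
        t=t,
        R_i=R_i,
        R_o=R_o,
        r_i=deformed.r_i,
        r_o=deformed.r_o,
        alpha=alpha,
        lam=deformed.r_o / R_o,
        v_c=v_c,
        E=E,
        P=P,
        mean_sigma_rr=mean_radial_stress(geom, P),
        mean_sigma_tt=mean_tangential_stress(geom, P),
        EDV=deformed.cavity_volume,
    )


def euler_step(state: WallState, config: SimulationConfig, step: int = 0) -> WallState:
    """Advance the wall by one explicit Euler step of ``config.step_months``.

    Order of operations: the growth law updates alpha and hence the free
    outer radius; the mass balance updates the free inner radius using
    quantities at the current time; drivers, modulus and pressure at the
    *new* time then determine the deformed configuration.
    """
    gp = config.growth
    h = config.step_months
    f = growth_rate(state.lam, state.t, config.t_start, gp)
    alpha_next = state.alpha + f * h
    R_o_next = alpha_next * config.R_o0
    R_o_dot = config.R_o0 * f
    b = volume_flux_b(config.drivers, config.materials, state.t)
    R_i_next = state.R_i + h * (state.R_o**2 * R_o_dot - b) / state.R_i**2
    t_next = config.t_start + (step + 1) * h
    if not 0.0 < R_i_next < R_o_next:
        raise GrowthSimulationError(
            f"free radii left the admissible region: R_i={R_i_next}, R_o={R_o_next}",
            step=step,
            t=t_next,
        )
    return _derived_state(t_next, R_i_next, R_o_next, alpha_next, config, step=step + 1)


def simulate(config: SimulationConfig) -> list[WallState]:
    """Integrate the aging trajectory; returns states at t0 + n*h, n=0..N."""
    state = _derived_state(config.t_start, config.R_i0, config.R_o0, 1.0, config, step=0)
    trajectory = [state]
    for n in range(config.n_steps):
        state = euler_step(state, config, step=n)
        trajectory.append(state)
    return trajectory


def trajectory_frame(trajectory: Sequence[WallState]) -> pd.DataFrame:
    """Tabulate a trajectory with the package's canonical column schema."""
    rows = {
        "t_months": [s.t for s in trajectory],
        "R_i_mm": [s.R_i for s in trajectory],
        "R_o_mm": [s.R_o for s in trajectory],
        "r_i_mm": [s.r_i for s in trajectory],
        "r_o_mm": [s.r_o for s in trajectory],
        "alpha": [s.alpha for s in trajectory],
        "lambda": [s.lam for s in trajectory],
        "v_c": [s.v_c for s in trajectory],
        "E_Pa": [s.E for s in trajectory],
        "P_mmHg": [s.P_mmHg for s in trajectory],
        "P_Pa": [s.P for s in trajectory],
        "mean_sigma_rr_Pa": [s.mean_sigma_rr for s in trajectory],
        "mean_sigma_tt_Pa": [s.mean_sigma_tt for s in trajectory],
        "EDV_mm3": [s.EDV for s in trajectory],
    }
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def max_outer_radius(config: SimulationConfig) -> float:
    """Largest admissible free outer radius at the end of the window.

    Computed from the final wall tissue volume V(t_end) = M_c/rho_c +
    M_m/rho_m with the inner radius held at its initial value (the least
    favourable admissible choice):  R_o,max^3 = R_i0^3 + 3 V / (4 pi).
    """
    d, m = config.drivers, config.materials
    volume = d.collagen_mass(config.t_end) / m.rho_collagen + d.muscle_mass(
        config.t_end
    ) / m.rho_muscle
    return (config.R_i0**3 + 3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class BoundsResult:
    """Admissibility bounds on the growth rate at one time point (1/month).

    The tight bounds use the realized radii; the universal bounds depend
    only on the drivers, the initial geometry, and the end-of-window
    outer-radius cap, so they can be checked before any simulation.
    """

    t: float
    tight_lower: float
    tight_upper: float
    universal_lower: float
    universal_upper: float
    f_actual: float

    @property
    def in_tight_band(self) -> bool:
        return self.tight_lower <= self.f_actual <= self.tight_upper

    @property
    def in_universal_band(self) -> bool:
        return self.universal_lower <= self.f_actual <= self.universal_upper


def growth_rate_bounds(
    trajectory: Sequence[WallState], config: SimulationConfig
) -> list[BoundsResult]:
    """Evaluate tight and universal growth-rate bands along a trajectory.

    tight_lower = b/(R_o0 R_o^2) keeps the inner radius non-decreasing;
    tight_upper = b/(R_o0 (R_o^2 - R_i^2)) keeps the thickness
    non-decreasing.  The universal band replaces the realized radii with
    their extreme admissible values: R_o >= R_o0 on the lower side and the
    end-of-window cap from :func:`max_outer_radius` on the upper side.
    """
    R_o0 = config.R_o0
    R_o_max = max_outer_radius(config)
    span = R_o_max**2 - config.R_i0**2
    if span <= 0:
        raise ValueError(
            f"outer-radius cap {R_o_max} does not exceed the initial inner radius"
        )
    results = []
    for s in trajectory:
        b = volume_flux_b(config.drivers, config.materials, s.t)
        f = growth_rate(s.lam, s.t, config.t_start, config.growth)
        results.append(
            BoundsResult(
                t=s.t,
                tight_lower=b / (R_o0 * s.R_o**2),
                tight_upper=b / (R_o0 * (s.R_o**2 - s.R_i**2)),
                universal_lower=b / R_o0**3,
                universal_upper=b / (R_o0 * span),
                f_actual=f,
            )
        )
    return results


def bounds_frame(bounds: Sequence[BoundsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_months": [b.t for b in bounds],
            "tight_lower": [b.tight_lower for b in bounds],
            "tight_upper": [b.tight_upper for b in bounds],
            "universal_lower": [b.universal_lower for b in bounds],
            "universal_upper": [b.universal_upper for b in bounds],
            "f_actual": [b.f_actual for b in bounds],
        }
    )


@dataclass
class AdmissibilityReport:
    """Report on whether a growth-rate function keeps remodeling monotone.

    ``admissible`` is the operational verdict used downstream (trajectory
    completes, outer radius and thickness non-decreasing, no net shrinkage
    of the inner radius).  Strict per-step band membership is reported
    separately: a rate that decays faster than the mass flux b(t) can
    leave the bands late in life while every geometric trend still holds
    to within micrometres — the report quantifies that with the maximum
    inner-radius dip.
    """

    admissible: bool
    universal_ok: bool
    tight_ok: bool
    monotone_R_i: bool
    monotone_R_o: bool
    monotone_thickness: bool
    first_universal_violation_t: float | None = None
    first_tight_violation_t: float | None = None
    max_R_i_dip_mm: float = 0.0
    net_R_i_change_mm: float = 0.0
    messages: list[str] = field(default_factory=list)


def check_growth_function(
    config: SimulationConfig, trajectory: Sequence[WallState] | None = None
) -> AdmissibilityReport:
    """Check the configured growth law against the admissibility bands.

    Simulates if no trajectory is supplied.  Report-only: violations are
    flagged with times and magnitudes, never raised.
    """
    messages: list[str] = []
    if trajectory is None:
        try:
            trajectory = simulate(config)
        except GrowthSimulationError as exc:
            return AdmissibilityReport(
                admissible=False,
                universal_ok=False,
                tight_ok=False,
                monotone_R_i=False,
                monotone_R_o=False,
                monotone_thickness=False,
                messages=[f"simulation failed: {exc}"],
            )
    bounds = growth_rate_bounds(trajectory, config)
    first_uni = next((b.t for b in bounds if not b.in_universal_band), None)
    first_tight = next((b.t for b in bounds if not b.in_tight_band), None)

    R_i = np.array([s.R_i for s in trajectory])
    R_o = np.array([s.R_o for s in trajectory])
    th = R_o - R_i
    monotone_R_i = bool(np.all(np.diff(R_i) >= 0))
    monotone_R_o = bool(np.all(np.diff(R_o) >= 0))
    monotone_th = bool(np.all(np.diff(th) >= 0))
    running_max = np.maximum.accumulate(R_i)
    max_dip = float(np.max(running_max - R_i))
    net = float(R_i[-1] - R_i[0])

    if first_uni is not None:
        messages.append(
            f"f(t) leaves the universal band at t={first_uni:.3f} months"
        )
    if first_tight is not None:
        messages.append(f"f(t) leaves the tight band at t={first_tight:.3f} months")
    if not monotone_R_i:
        messages.append(
            f"inner radius is not monotone: max dip {max_dip:.3e} mm "
            f"({100 * max_dip / float(np.max(R_i)):.4f}% of its peak)"
        )
    if not monotone_R_o:
        messages.append("outer radius is not monotone")
    if not monotone_th:
        messages.append("wall thickness is not monotone")

    admissible = monotone_R_o and monotone_th and net >= 0
    return AdmissibilityReport(
        admissible=admissible,
        universal_ok=first_uni is None,
        tight_ok=first_tight is None,
        monotone_R_i=monotone_R_i,
        monotone_R_o=monotone_R_o,
        monotone_thickness=monotone_th,
        first_universal_violation_t=first_uni,
        first_tight_violation_t=first_tight,
        max_R_i_dip_mm=max_dip,
        net_R_i_change_mm=net,
        messages=messages,
    )
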