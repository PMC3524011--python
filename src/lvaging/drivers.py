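"""Temporal input functions and composite-wall material relations.

The aging simulation is driven by three fitted, saturating-exponential
curves: total left-ventricular (LV) mass, collagen mass (both mg), and
transmural pressure (mmHg), each of the form

    f(t) = A + B * (1 - exp(-(t - t_s) / tau)),

with *t* in months.  Muscle (myocyte) mass is defined as total minus
collagen mass, never fitted independently.  The wall is a two-constituent
composite (collagen + myocytes); its Young's modulus follows the rule of
mixtures over the collagen volume fraction.

Unit conventions used throughout the package: lengths mm, masses mg, time
months, moduli and pressures Pa.  Densities in g/cm^3 equal mg/mm^3
exactly, so no conversion is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MMHG_TO_PA",
    "SaturatingExponential",
    "MaterialParams",
    "DriverSet",
    "eval_driver",
    "eval_driver_rate",
    "collagen_volume_fraction",
    "composite_modulus",
    "pressure_pa",
    "volume_flux_b",
    "collagen_fraction_at",
    "modulus_at",
]

#: Conversion factor from mmHg to Pa (1 mmHg = 133.322 Pa).
MMHG_TO_PA = 133.322


@dataclass(frozen=True)
class SaturatingExponential:
    """Monotone driver ``A + B*(1 - exp(-(t - t_s)/tau))``.

    Parameters
    ----------
    base : float
        Value A at the onset time (mg or mmHg).
    amplitude : float
        Saturation amplitude B; the driver tends to ``A + B`` as t -> inf.
        Non-negative for the non-decreasing drivers used here.
    onset_months : float
        Onset time t_s (months).  Evaluation before t_s is permitted (the
        reference simulation starts at 7.5 months with a total-mass onset
        of 8.18 months).
    tau_months : float
        Characteristic saturation time tau (months), strictly positive.
    """

    base: float
    amplitude: float
    onset_months: float
    tau_months: float

    def __post_init__(self) -> None:
        if not self.tau_months > 0:
            raise ValueError(f"tau_months must be > 0, got {self.tau_months}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")

    def __call__(self, t):
        """Evaluate the driver at time ``t`` (months)."""
        t = np.asarray(t, dtype=float)
        out = self.base + self.amplitude * (
            1.0 - np.exp(-(t - self.onset_months) / self.tau_months)
        )
        return out if out.ndim else float(out)

    def rate(self, t):
        """Analytic time derivative ``(B/tau) * exp(-(t - t_s)/tau)``."""
        t = np.asarray(t, dtype=float)
        out = (self.amplitude / self.tau_months) * np.exp(
            -(t - self.onset_months) / self.tau_months
        )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class MaterialParams:
    """Densities and elastic constants of the two-constituent wall.

    ``rho_collagen`` and ``rho_muscle`` are in mg/mm^3 (numerically equal
    to g/cm^3), ``E_collagen`` and ``E_muscle`` in Pa, ``poisson`` is the
    composite Poisson ratio.  Stable, non-auxetic soft tissue requires
    0 < nu < 0.5; collagen must be stiffer than muscle.
    """

    rho_collagen: float = 1.70
    rho_muscle: float = 1.06
    E_collagen: float = 3.2e7
    E_muscle: float = 5.0e4
    poisson: float = 0.47

    def __post_init__(self) -> None:
        if not 0.0 < self.poisson < 0.5:
            raise ValueError(f"poisson must lie in (0, 0.5), got {self.poisson}")
        for name in ("rho_collagen", "rho_muscle", "E_collagen", "E_muscle"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.E_collagen > self.E_muscle:
            raise ValueError("E_collagen must exceed E_muscle")


@dataclass(frozen=True)
class DriverSet:
    """The three fitted temporal drivers of the aging simulation.

    Muscle mass is *defined* as ``total_mass(t) - collagen_mass(t)`` and
    must stay positive on the simulation window.
    """

    total_mass: SaturatingExponential
    collagen_mass: SaturatingExponential
    pressure: SaturatingExponential

    def muscle_mass(self, t):
        return self.total_mass(t) - self.collagen_mass(t)

    def muscle_mass_rate(self, t):
        return self.total_mass.rate(t) - self.collagen_mass.rate(t)


def eval_driver(f: SaturatingExponential, t):
    """Evaluate a driver at time ``t`` (months)."""
    return f(t)


def eval_driver_rate(f: SaturatingExponential, t):
    """Analytic time derivative of a driver at ``t`` (unit/month)."""
    return f.rate(t)


def collagen_volume_fraction(m_collagen, m_muscle, mat: MaterialParams):
    """Collagen volume fraction of the wall composite.

    v_c = (M_c/rho_c) / (M_c/rho_c + M_m/rho_m), in [0, 1) for positive
    muscle mass.  Masses in mg.
    """
    m_collagen = np.asarray(m_collagen, dtype=float)
    m_muscle = np.asarray(m_muscle, dtype=float)
    if np.any(m_collagen < 0):
        raise ValueError("collagen mass must be >= 0")
    if np.any(m_muscle <= 0):
        raise ValueError("muscle mass must be > 0")
    vc = m_collagen / mat.rho_collagen
    vm = m_muscle / mat.rho_muscle
    out = vc / (vc + vm)
    return out if out.ndim else float(out)


def composite_modulus(v_c, mat: MaterialParams):
    """Rule-of-mixtures Young's modulus ``E_c*v_c + E_m*(1 - v_c)`` (Pa)."""
    v_c = np.asarray(v_c, dtype=float)
    if np.any((v_c < 0) | (v_c > 1)):
        raise ValueError("collagen volume fraction must lie in [0, 1]")
    out = mat.E_collagen * v_c + mat.E_muscle * (1.0 - v_c)
    return out if out.ndim else float(out)


def pressure_pa(drivers: DriverSet, t):
    """Transmural pressure at ``t`` in Pa (driver is fitted in mmHg)."""
    p = np.asarray(drivers.pressure(t), dtype=float) * MMHG_TO_PA
    return p if p.ndim else float(p)


def volume_flux_b(drivers: DriverSet, mat: MaterialParams, t):
    """Volumetric mass-flux term b(t) of the free-radius balance.

    b(t) = [dM_c/dt + (rho_c/rho_m) dM_m/dt] / (4 pi rho_c), equal to
    (1/4pi) d/dt of the wall tissue volume (mm^3/month).  Non-negative
    whenever both mass drivers are non-decreasing.
    """
    mc_dot = np.asarray(drivers.collagen_mass.rate(t), dtype=float)
    mm_dot = np.asarray(drivers.muscle_mass_rate(t), dtype=float)
    out = (mc_dot + (mat.rho_collagen / mat.rho_muscle) * mm_dot) / (
        4.0 * np.pi * mat.rho_collagen
    )
    return out if out.ndim else float(out)


def collagen_fraction_at(drivers: DriverSet, mat: MaterialParams, t):
    """Collagen volume fraction implied by the drivers at time ``t``."""
    return collagen_volume_fraction(drivers.collagen_mass(t), drivers.muscle_mass(t), mat)


def modulus_at(drivers: DriverSet, mat: MaterialParams, t):
    """Composite Young's modulus (Pa) implied by the drivers at ``t``."""
    return composite_modulus(collagen_fraction_at(drivers, mat, t), mat)
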