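"""Linear elastostatics of a pressurized thick-walled sphere (Lamé solution).

The LV wall at end diastole is idealized as an isotropic, homogeneous,
linearly elastic spherical shell with free (no-load) radii ``R_i < R_o``,
loaded by a transmural pressure P on the inner surface (outer surface
traction-free).  Closed forms for the stress field, the radial strain, the
deformed wall thickness, and wall-averaged stresses follow; the deformed
radii are recovered from the deformed thickness together with exact volume
conservation ``r_o^3 - r_i^3 = R_o^3 - R_i^3``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "WallGeometry",
    "DeformedGeometry",
    "InadmissibleGeometryError",
    "radial_stress",
    "tangential_stress",
    "radial_strain",
    "deformed_thickness",
    "solve_deformed_radii",
    "mean_radial_stress",
    "mean_tangential_stress",
]


class InadmissibleGeometryError(ValueError):
    """Raised when requested geometry or loading is unphysical."""


@dataclass(frozen=True)
class WallGeometry:
    """Free (no-load) shell radii in mm, ``0 < R_i < R_o``."""

    R_i: float
    R_o: float

    def __post_init__(self) -> None:
        if not 0.0 < self.R_i < self.R_o:
            raise InadmissibleGeometryError(
                f"need 0 < R_i < R_o, got R_i={self.R_i}, R_o={self.R_o}"
            )

    @property
    def thickness(self) -> float:
        return self.R_o - self.R_i

    @property
    def cubic_gap(self) -> float:
        """The shell's cubic gap d = R_o^3 - R_i^3 (mm^3)."""
        return self.R_o**3 - self.R_i**3

    @property
    def ratio(self) -> float:
        """Radius ratio k = R_o / R_i (> 1)."""
        return self.R_o / self.R_i


@dataclass(frozen=True)
class DeformedGeometry:
    """Deformed (loaded) shell radii in mm, ``0 < r_i < r_o``."""

    r_i: float
    r_o: float

    def __post_init__(self) -> None:
        if not 0.0 < self.r_i < self.r_o:
            raise InadmissibleGeometryError(
                f"need 0 < r_i < r_o, got r_i={self.r_i}, r_o={self.r_o}"
            )

    @property
    def thickness(self) -> float:
        return self.r_o - self.r_i

    @property
    def cavity_volume(self) -> float:
        """End-diastolic cavity volume (4/3) pi r_i^3 (mm^3)."""
        return 4.0 / 3.0 * math.pi * self.r_i**3


def _check_radius(geom: WallGeometry, R: float) -> None:
    if not geom.R_i <= R <= geom.R_o:
        raise InadmissibleGeometryError(
            f"R={R} outside the wall [{geom.R_i}, {geom.R_o}]"
        )


def radial_stress(geom: WallGeometry, P: float, R: float) -> float:
    """Radial Cauchy stress sigma_RR(R) in Pa.

    sigma_RR = P R_i^3 / (R_o^3 - R_i^3) * (1 - R_o^3/R^3); equals -P at
    the inner surface and 0 at the traction-free outer surface, and is
    compressive (<= 0) throughout for P > 0.
    """
    _check_radius(geom, R)
    return P * geom.R_i**3 / geom.cubic_gap * (1.0 - geom.R_o**3 / R**3)


def tangential_stress(geom: WallGeometry, P: float, R: float) -> float:
    """Tangential stress sigma_tt(R) = sigma_pp(R) in Pa (tensile for P > 0).

    sigma_tt = P R_i^3 / (R_o^3 - R_i^3) * (1 + R_o^3/(2 R^3)).
    """
    _check_radius(geom, R)
    return P * geom.R_i**3 / geom.cubic_gap * (1.0 + geom.R_o**3 / (2.0 * R**3))


def radial_strain(geom: WallGeometry, P: float, E: float, nu: float, R: float) -> float:
    """Radial strain dr/dR - 1 from Hooke's law applied to the Lamé field.

    Returns (P/E) / (k^3 - 1) * [(1 - 2 nu) - (1 + nu) (R_o/R)^3] with
    k = R_o/R_i; negative through the wall for P > 0 and nu < 0.5 (the
    loaded wall is thinner than the free wall).
    """
    if not E > 0:
        raise InadmissibleGeometryError(f"Young's modulus must be > 0, got {E}")
    _check_radius(geom, R)
    k3 = geom.ratio**3
    return P / E / (k3 - 1.0) * ((1.0 - 2.0 * nu) - (1.0 + nu) * (geom.R_o / R) ** 3)


def deformed_thickness(geom: WallGeometry, P: float, E: float, nu: float) -> float:
    """Loaded wall thickness c = r_o - r_i in mm.

    Exact integral of (1 + radial strain) across the wall:

        c = (R_o - R_i) * {1 - (P/E)/(k^3 - 1) * [(1+nu)(k^2 + k)/2 - (1 - 2 nu)]}

    with k = R_o/R_i.  Strictly smaller than the free thickness for P > 0
    and 0 < nu < 0.5.
    """
    if not E > 0:
        raise InadmissibleGeometryError(f"Young's modulus must be > 0, got {E}")
    k = geom.ratio
    bracket = (1.0 + nu) * (k * k + k) / 2.0 - (1.0 - 2.0 * nu)
    c = geom.thickness * (1.0 - P / E / (k**3 - 1.0) * bracket)
    if not c > 0:
        raise InadmissibleGeometryError(
            f"deformed thickness {c} <= 0: pressure too large relative to modulus"
        )
    return c


def solve_deformed_radii(c: float, d: float) -> DeformedGeometry:
    """Deformed radii from thickness ``c`` and cubic gap ``d``.

    Solves r_o - r_i = c and r_o^3 - r_i^3 = d by the explicit radical

        r_i = (-c + sqrt((4 d / c - c^2) / 3)) / 2,    r_o = r_i + c,

    which requires c > 0 and d > c^3 for a positive inner radius.
    """
    if not c > 0:
        raise InadmissibleGeometryError(f"deformed thickness must be > 0, got {c}")
    if not d > c**3:
        raise InadmissibleGeometryError(
            f"need cubic gap d > c^3 for a positive inner radius (d={d}, c^3={c**3})"
        )
    r_i = 0.5 * (-c + math.sqrt((4.0 * d / c - c * c) / 3.0))
    return DeformedGeometry(r_i=r_i, r_o=r_i + c)


def mean_radial_stress(geom: WallGeometry, P: float) -> float:
    """Wall-averaged radial stress in Pa (negative for P > 0).

    <sigma_RR> = -P R_i (R_o + 2 R_i) / (2 (R_o^2 + R_o R_i + R_i^2)).
    """
    Ri, Ro = geom.R_i, geom.R_o
    return -P * Ri * (Ro + 2.0 * Ri) / (2.0 * (Ro * Ro + Ro * Ri + Ri * Ri))


def mean_tangential_stress(geom: WallGeometry, P: float) -> float:
    """Wall-averaged tangential stress in Pa (positive for P > 0).

    <sigma_tt> = P R_i (R_o^2 + R_o R_i + 4 R_i^2) / (4 (R_o^3 - R_i^3)).
    """
    Ri, Ro = geom.R_i, geom.R_o
    return P * Ri * (Ro * Ro + Ro * Ri + 4.0 * Ri * Ri) / (4.0 * geom.cubic_gap)
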