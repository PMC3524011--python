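"""Trajectory post-processing: EDPVR curve and the life-span summary."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .drivers import MMHG_TO_PA
from .growth import SimulationConfig, WallState

__all__ = ["SummaryReport", "edpvr", "summarize"]


def edpvr(trajectory: Sequence[WallState]) -> pd.DataFrame:
    """End-diastolic pressure-volume relation traced by aging.

    Each aging time point contributes one (EDV, P) pair: the cavity volume
    (4/3) pi r_i^3 from the deformed inner radius against the transmural
    pressure in mmHg.  This is a trajectory across the life span, not a
    within-beat P-V loop; along the reference trajectory both coordinates
    increase with age and the local slope indexes passive LV stiffening.
    """
    if not trajectory:
        raise ValueError("trajectory is empty")
    return pd.DataFrame(
        {
            "t_months": [s.t for s in trajectory],
            "EDV_mm3": [s.EDV for s in trajectory],
            "P_mmHg": [s.P_mmHg for s in trajectory],
        }
    )


@dataclass(frozen=True)
class SummaryReport:
    """Window-wide percent changes and endpoint values of one trajectory.

    Percent changes are 100*(final - initial)/initial over the simulated
    window; deformation percentages are the maximum over time of
    100*|r - R|/R for each surface.
    """

    pct_inner_radius: float
    pct_outer_radius: float
    pct_wall_thickness: float
    pct_total_mass: float
    pct_collagen_mass: float
    pct_muscle_mass: float
    pct_modulus: float
    max_deformation_inner_pct: float
    max_deformation_outer_pct: float
    inner_radius_initial_mm: float
    inner_radius_final_mm: float
    wall_thickness_initial_mm: float
    wall_thickness_final_mm: float
    pressure_final_mmHg: float
    pressure_final_Pa: float

    def to_dict(self) -> dict:
        return asdict(self)


def _pct(final: float, initial: float) -> float:
    return 100.0 * (final - initial) / initial


def summarize(
    trajectory: Sequence[WallState], config: SimulationConfig
) -> SummaryReport:
    """Summarize a trajectory spanning the configured window.

    The config supplies the mass drivers; geometric quantities come from
    the trajectory itself.
    """
    if not trajectory:
        raise ValueError("trajectory is empty")
    first, last = trajectory[0], trajectory[-1]
    d = config.drivers
    t0, t1 = first.t, last.t

    dev_i = 100.0 * np.max([abs(s.r_i - s.R_i) / s.R_i for s in trajectory])
    dev_o = 100.0 * np.max([abs(s.r_o - s.R_o) / s.R_o for s in trajectory])

    return SummaryReport(
        pct_inner_radius=_pct(last.R_i, first.R_i),
        pct_outer_radius=_pct(last.R_o, first.R_o),
        pct_wall_thickness=_pct(last.thickness, first.thickness),
        pct_total_mass=_pct(d.total_mass(t1), d.total_mass(t0)),
        pct_collagen_mass=_pct(d.collagen_mass(t1), d.collagen_mass(t0)),
        pct_muscle_mass=_pct(d.muscle_mass(t1), d.muscle_mass(t0)),
        pct_modulus=_pct(last.E, first.E),
        max_deformation_inner_pct=float(dev_i),
        max_deformation_outer_pct=float(dev_o),
        inner_radius_initial_mm=first.R_i,
        inner_radius_final_mm=last.R_i,
        wall_thickness_initial_mm=first.thickness,
        wall_thickness_final_mm=last.thickness,
        pressure_final_mmHg=last.P / MMHG_TO_PA,
        pressure_final_Pa=last.P,
    )
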