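"""Diagnostic plots: geometry trajectories, EDPVR, and growth-rate bands."""

from __future__ import annotations

from typing import Sequence

from .growth import BoundsResult, SimulationConfig, WallState
from .analysis import edpvr as _edpvr


def plot_geometry(trajectory: Sequence[WallState], ax=None):
    """Free and deformed radii and wall thickness versus age."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = [s.t for s in trajectory]
    ax.plot(t, [s.R_o for s in trajectory], label="$R_o$ (free)")
    ax.plot(t, [s.r_o for s in trajectory], "--", label="$r_o$ (deformed)")
    ax.plot(t, [s.R_i for s in trajectory], label="$R_i$ (free)")
    ax.plot(t, [s.r_i for s in trajectory], "--", label="$r_i$ (deformed)")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("radius (mm)")
    ax.legend()
    return ax


def plot_edpvr(trajectory: Sequence[WallState], ax=None):
    """End-diastolic pressure-volume relation traced by aging."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curve = _edpvr(trajectory)
    ax.plot(curve["EDV_mm3"], curve["P_mmHg"], marker=".", markevery=0.1)
    ax.set_xlabel("end-diastolic volume (mm$^3$)")
    ax.set_ylabel("transmural pressure (mmHg)")
    return ax


def plot_bounds(bounds: Sequence[BoundsResult], ax=None, log: bool = True):
    """Growth rate f(t) against the tight and universal admissibility bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = [b.t for b in bounds]
    ax.plot(t, [b.f_actual for b in bounds], "c:", label="f(t)")
    ax.plot(t, [b.tight_lower for b in bounds], "k", label="tight lower")
    ax.plot(t, [b.tight_upper for b in bounds], "b", label="tight upper")
    ax.plot(t, [b.universal_lower for b in bounds], "g", label="universal lower")
    ax.plot(t, [b.universal_upper for b in bounds], "r", label="universal upper")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("age (months)")
    ax.set_ylabel("growth rate (1/month)")
    ax.legend()
    return ax
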