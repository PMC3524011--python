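"""Euler aging simulation, growth-rate bounds, and the admissibility report."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from lvaging import (
    GrowthLawParams,
    GrowthSimulationError,
    check_growth_function,
    growth_rate,
    growth_rate_bounds,
    simulate,
    trajectory_frame,
    volume_flux_b,
)
from lvaging.growth import euler_step, max_outer_radius

REF_GP = GrowthLawParams(tau_R=0.22, D=2.5, tau_f=5.6)


class TestGrowthRate:
    def test_no_stretch_no_growth(self):
        assert growth_rate(1.0, 12.0, 7.5, REF_GP) == 0.0

    def test_decays_to_zero(self):
        assert growth_rate(1.001, 1e4, 7.5, REF_GP) == pytest.approx(0.0, abs=1e-300)

    def test_reference_value_at_onset(self):
        lam = 1.000671
        expected = (lam**2.5 - 1.0) / 0.22  # exp factor is 1 at t0
        assert growth_rate(lam, 7.5, 7.5, REF_GP) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(7.6e-3, abs=1e-4)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            growth_rate(0.0, 7.5, 7.5, REF_GP)


class TestEulerStep:
    def test_static_configuration_is_a_fixed_point(self, static_config):
        state = simulate(static_config)[0]
        assert state.lam == pytest.approx(1.0, rel=1e-14)
        nxt = euler_step(state, static_config, step=0)
        assert nxt.R_i == state.R_i
        assert nxt.R_o == state.R_o

    def test_single_step_outer_radius_increment(self, config):
        state = simulate(config)[0]
        f0 = growth_rate(state.lam, state.t, config.t_start, config.growth)
        nxt = euler_step(state, config, step=0)
        assert nxt.R_o - state.R_o == pytest.approx(
            config.R_o0 * f0 * config.step_months, rel=1e-12
        )

    def test_step_volume_bookkeeping(self, config):
        # free-shell volume gain per step tracks 4 pi b h to first order
        state = simulate(config)[0]
        nxt = euler_step(state, config, step=0)
        h = config.step_months
        b = volume_flux_b(config.drivers, config.materials, state.t)
        dV = (
            4 * math.pi / 3 * ((nxt.R_o**3 - nxt.R_i**3) - (state.R_o**3 - state.R_i**3))
        )
        assert dV == pytest.approx(4 * math.pi * b * h, rel=5e-3)


class TestReferenceTrajectory:
    """The full C57BL/6J run: 7.5 -> 30 months, 3-hour Euler steps."""

    def test_initial_state(self, trajectory, config):
        first = trajectory[0]
        assert first.t == config.t_start
        assert first.alpha == 1.0
        assert first.lam == pytest.approx(1.0006639, abs=1e-6)

    def test_endpoint_geometry(self, trajectory):
        last = trajectory[-1]
        assert last.R_i == pytest.approx(2.042565, abs=1e-4)
        assert last.R_o == pytest.approx(3.018010, abs=1e-4)
        assert last.thickness == pytest.approx(0.975446, abs=1e-4)

    def test_stretch_ratio_exceeds_one_throughout(self, trajectory):
        assert all(s.lam > 1.0 for s in trajectory)

    def test_incompressibility_at_every_step(self, trajectory):
        for s in trajectory[::50]:
            free = s.R_o**3 - s.R_i**3
            deformed = s.r_o**3 - s.r_i**3
            assert deformed == pytest.approx(free, rel=1e-10)

    def test_deformation_stays_small(self, trajectory):
        dev_i = max(abs(s.r_i - s.R_i) / s.R_i for s in trajectory)
        dev_o = max(abs(s.r_o - s.R_o) / s.R_o for s in trajectory)
        assert dev_i < 0.005
        assert dev_o < 0.005

    def test_wall_volume_budget(self, trajectory, config):
        total, _ = quad(
            lambda t: 4 * math.pi * volume_flux_b(config.drivers, config.materials, t),
            config.t_start,
            config.t_end,
            limit=200,
        )
        first, last = trajectory[0], trajectory[-1]
        dV = (
            4 * math.pi / 3
            * ((last.R_o**3 - last.R_i**3) - (first.R_o**3 - first.R_i**3))
        )
        assert dV == pytest.approx(total, rel=0.01)

    def test_outer_radius_and_thickness_monotone(self, trajectory):
        R_o = np.array([s.R_o for s in trajectory])
        th = np.array([s.R_o - s.R_i for s in trajectory])
        assert np.all(np.diff(R_o) >= 0)
        assert np.all(np.diff(th) >= 0)

    def test_inner_radius_net_growth_with_micron_scale_late_dip(self, trajectory):
        # R_i rises ~2.1% overall but crests near 20.3 months and relaxes
        # by <1e-3 mm afterwards, because the growth rate decays faster
        # (tau_f = 5.6) than the mass flux b(t) (tau ~ 6.1-7.2).
        R_i = np.array([s.R_i for s in trajectory])
        assert R_i[-1] > R_i[0]
        dip = np.max(np.maximum.accumulate(R_i) - R_i)
        assert 0 < dip < 1e-3

    def test_zero_growth_control_keeps_geometry_frozen(self, static_config):
        slow = static_config.replace(growth=GrowthLawParams(tau_R=1e12, D=2.5, tau_f=5.6))
        traj = simulate(slow)
        assert traj[-1].R_i == pytest.approx(traj[0].R_i, abs=1e-9)
        assert traj[-1].R_o == pytest.approx(traj[0].R_o, abs=1e-9)

    def test_step_halving_barely_moves_endpoints(self, coarse_config):
        a = simulate(coarse_config)[-1]
        b = simulate(coarse_config.replace(step_hours=coarse_config.step_hours / 2))[-1]
        assert abs(b.R_i - a.R_i) / a.R_i < 1e-4
        assert abs(b.R_o - a.R_o) / a.R_o < 1e-4

    def test_trajectory_frame_schema(self, trajectory):
        frame = trajectory_frame(trajectory[:5])
        assert list(frame.columns) == [
            "t_months", "R_i_mm", "R_o_mm", "r_i_mm", "r_o_mm", "alpha",
            "lambda", "v_c", "E_Pa", "P_mmHg", "P_Pa",
            "mean_sigma_rr_Pa", "mean_sigma_tt_Pa", "EDV_mm3",
        ]
        assert len(frame) == 5

    def test_simulation_abort_carries_step_context(self, config):
        # a pressure four orders of magnitude too high collapses the wall
        from lvaging import DriverSet, SaturatingExponential

        bad = config.replace(
            drivers=DriverSet(
                total_mass=config.drivers.total_mass,
                collagen_mass=config.drivers.collagen_mass,
                pressure=SaturatingExponential(5e4, 0.0, 0.0, 1.0),
            )
        )
        with pytest.raises(GrowthSimulationError):
            simulate(bad)


class TestGrowthRateBounds:
    def test_outer_radius_cap_from_final_tissue_volume(self, config):
        # V(30) = M_c/rho_c + M_m/rho_m ~ 79.77 mm^3 with R_i frozen at 2.0
        assert max_outer_radius(config) == pytest.approx(3.00164, abs=1e-4)

    def test_universal_band_at_ten_months(self, trajectory, config):
        bounds = growth_rate_bounds(trajectory, config)
        at_10 = min(bounds, key=lambda b: abs(b.t - 10.0))
        assert at_10.universal_lower == pytest.approx(3.112e-3, abs=2e-5)
        assert at_10.universal_upper == pytest.approx(5.297e-3, abs=2e-5)
        assert at_10.f_actual == pytest.approx(4.053e-3, abs=2e-5)
        assert at_10.in_universal_band

    def test_band_ordering(self, trajectory, config):
        for b in growth_rate_bounds(trajectory, config)[::100]:
            assert b.universal_lower <= b.universal_upper
            assert b.tight_lower <= b.tight_upper
            # the universal band is the stricter, trajectory-free band
            assert b.tight_lower <= b.universal_lower
            assert b.universal_upper <= b.tight_upper

    def test_zero_flux_collapses_bounds(self, static_config):
        traj = simulate(static_config)
        for b in growth_rate_bounds(traj, static_config):
            assert b.tight_lower == b.tight_upper == 0.0
            assert b.universal_lower == b.universal_upper == 0.0
            assert b.f_actual == 0.0


class TestAdmissibilityReport:
    def test_reference_parameters_admissible_with_late_band_exit(self, config, trajectory):
        report = check_growth_function(config, trajectory)
        assert report.admissible
        assert report.monotone_R_o
        assert report.monotone_thickness
        assert report.net_R_i_change_mm > 0
        # the exponentially decaying rate leaves the bands late in life
        assert not report.universal_ok
        assert report.first_universal_violation_t == pytest.approx(17.13, abs=0.05)
        assert report.first_tight_violation_t == pytest.approx(20.34, abs=0.05)
        assert report.max_R_i_dip_mm == pytest.approx(7.5e-4, abs=1e-4)
        assert report.messages  # violations are surfaced, not hidden

    def test_vanishing_growth_rate_flagged_as_shrinkage(self, coarse_config):
        # f ~ 0 with b > 0 forces the inner radius to recede
        frozen = coarse_config.replace(
            growth=GrowthLawParams(tau_R=1e9, D=2.5, tau_f=5.6)
        )
        report = check_growth_function(frozen)
        assert not report.admissible
        assert not report.monotone_R_i
        assert report.net_R_i_change_mm < 0

    def test_static_system_trivially_admissible(self, static_config):
        report = check_growth_function(static_config)
        assert report.admissible
        assert report.universal_ok and report.tight_ok
        assert report.monotone_R_i and report.monotone_R_o and report.monotone_thickness
        assert report.messages == []
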