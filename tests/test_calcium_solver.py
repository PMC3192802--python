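"""The assembled reaction-diffusion system and its conservation laws."""

import numpy as np
import pytest

from dendrocrowd.calcium import (
    CALCINEURIN,
    CALMODULIN,
    ReactionSystemSpec,
    SpineSinkSpec,
    assemble_and_solve,
    buffer_equilibrium,
    measure_spread,
    run_scenario,
)
from dendrocrowd.calcium.spread import profile_fwhm
from dendrocrowd.reduced import solve_reduced_1d
from dendrocrowd.units import concentration_to_linear_density


def _pulse(center, peak=1.0, sigma=0.5):
    return lambda x: peak * np.exp(-((x - center) ** 2) / (2 * sigma**2))


class TestPureDiffusion:
    def test_matches_reduced_solver(self):
        system = ReactionSystemSpec(
            length=20.0, D_ca=20.0, buffers=(), dye=None, pumps=()
        )
        traj = assemble_and_solve(system, 0.01, ca_profile=_pulse(10.0), n_save=6)
        x = traj.grid
        c0 = concentration_to_linear_density(_pulse(10.0)(x), system.cross_section)
        ref = solve_reduced_1d(c0, x, traj.times, D=20.0, bc="reflecting")
        np.testing.assert_allclose(
            traj.free_ca()[-1], ref.values[-1], rtol=5e-3, atol=1e-3 * c0.max()
        )

    def test_total_calcium_conserved_without_sinks(self):
        system = ReactionSystemSpec(length=10.0, D_ca=20.0, pumps=(), dye=None)
        traj = assemble_and_solve(system, 0.02, ca_profile=_pulse(5.0), n_save=5)
        b = traj.budget()
        total = b["free"] + b["bound"]
        np.testing.assert_allclose(total, total[0], rtol=1e-6)

    def test_densities_stay_nonnegative(self):
        traj, _ = run_scenario("fig4d", {"n_save": 11})
        assert traj.free_ca().min() >= 0.0
        assert traj.bound_dye().min() >= 0.0


class TestBufferedEquilibria:
    def test_uniform_system_relaxes_to_mass_action_equilibrium(self):
        """Buffers on, pumps off, uniform calcium: occupancies approach the
        closed-form equilibrium of the coupled mass-action system."""
        system = ReactionSystemSpec(
            length=2.0, D_ca=20.0, buffers=(CALCINEURIN,), dye=None, pumps=()
        )
        c_total = 0.8  # μM of calcium added uniformly
        traj = assemble_and_solve(
            system, 2.0, ca_profile=lambda x: c_total, n_save=5
        )
        c_free = traj.free_ca_concentration()[-1].mean()
        # solve the scalar equilibrium: c + B(c) = c_total with
        # B(c) = B_tot · (2c)/(1 + 2c) (CN: kf/kb = 2 per μM)
        from scipy.optimize import brentq

        b_tot = CALCINEURIN.total_concentration
        g = lambda c: c + b_tot * 2 * c / (1 + 2 * c) - c_total  # noqa: E731
        c_eq = brentq(g, 1e-12, c_total)
        assert c_free == pytest.approx(c_eq, rel=1e-3)
        occ = traj.buffer_states("calcineurin")[-1].mean(axis=1)
        expected = buffer_equilibrium(CALCINEURIN, c_eq)
        np.testing.assert_allclose(occ / occ.sum(), expected, rtol=1e-3)

    def test_per_node_buffer_total_is_constant(self):
        traj, _ = run_scenario("fig4d", {"n_save": 11})
        for name in ("calmodulin", "calcineurin"):
            states = traj.buffer_states(name)
            totals = states.sum(axis=1)  # (nt, nx)
            np.testing.assert_allclose(
                totals, np.broadcast_to(totals[0], totals.shape), rtol=1e-6
            )


class TestDirectionalClaims:
    def test_crowded_pulse_stays_higher_at_origin_than_aqueous(self):
        """Slower dilution: the crowded-peak amplitude dominates at matched
        times (bare diffusion, D = 20 vs 400 μm²/s)."""
        aq, _ = run_scenario("fig4a", {"n_save": 11})
        cr, _ = run_scenario("fig4b", {"n_save": 11})
        mid = aq.grid.size // 2
        assert np.all(
            cr.free_ca()[1:, mid] >= aq.free_ca()[1:, mid]
        )

    def test_crowded_transient_more_localized_and_longer_lasting(self):
        aq, _ = run_scenario("fig4c", {"n_save": 21})
        cr, _ = run_scenario("fig4d", {"n_save": 21})
        f_aq = profile_fwhm(aq.grid, aq.free_ca()[5])
        f_cr = profile_fwhm(cr.grid, cr.free_ca()[5])
        assert f_cr < f_aq
        mid = aq.grid.size // 2
        assert cr.free_ca()[-1, mid] > aq.free_ca()[-1, mid]

    def test_buffers_and_pumps_accelerate_decay_at_origin(self):
        """Time to 10% of peak at the origin is shorter with buffers on."""
        bare, _ = run_scenario("fig4b", {"n_save": 41, "t_end": 0.02})
        buff, _ = run_scenario("fig4d", {"n_save": 41, "t_end": 0.02})
        mid = bare.grid.size // 2

        def t10(traj):
            c = traj.free_ca()[:, mid]
            below = np.nonzero(c < 0.1 * c[0])[0]
            return traj.times[below[0]] if below.size else np.inf

        assert t10(buff) < t10(bare)

    def test_buffer_dominance_over_crowding(self):
        """Sensitivity of the spread to buffer level exceeds its
        sensitivity to the 20× crowding factor (both pumps on)."""
        from dataclasses import replace

        low = {"buffers": (replace(CALMODULIN, total_concentration=10.0),
                           replace(CALCINEURIN, total_concentration=5.0))}
        high = {"buffers": (replace(CALMODULIN, total_concentration=100.0),
                            replace(CALCINEURIN, total_concentration=25.0))}

        def spread_of(name, overrides):
            traj, rep = run_scenario(name, {"n_save": 21, **overrides})
            return rep["max_spread_um"]

        s_crowded = spread_of("fig4d", {})
        s_aqueous = spread_of("fig4c", {})
        s_low = spread_of("fig4d", low)
        s_high = spread_of("fig4d", high)
        crowding_sensitivity = abs(s_aqueous - s_crowded) / s_crowded
        buffer_sensitivity = abs(s_low - s_high) / s_high
        assert buffer_sensitivity > crowding_sensitivity


class TestSpinesAndBudget:
    def test_spine_absorption_closes_the_budget(self):
        system = ReactionSystemSpec(
            length=10.0, D_ca=20.0, buffers=(), dye=None, pumps=(),
            spines=SpineSinkSpec(neck_radius=0.1, positions=(5.0,)),
        )
        traj = assemble_and_solve(system, 0.05, ca_profile=_pulse(5.0), n_save=11)
        b = traj.budget()
        assert b["spines"][-1] > 0  # the spine removed calcium
        assert b["relative_closure_error"].max() < 1e-6

    def test_zero_spine_density_means_no_sink(self):
        system = ReactionSystemSpec(
            length=10.0, D_ca=20.0, buffers=(), dye=None, pumps=(),
            spines=SpineSinkSpec(neck_radius=0.1, positions=()),
        )
        traj = assemble_and_solve(system, 0.01, ca_profile=_pulse(5.0), n_save=5)
        assert traj.budget()["spines"][-1] == 0.0


class TestGridConvergence:
    def test_halving_dx_changes_spread_by_less_than_two_percent(self):
        coarse, rep_c = run_scenario("fig4d", {"n_save": 11})
        fine, rep_f = run_scenario("fig4d", {"n_save": 11, "dx": 0.025})
        assert rep_f["max_spread_um"] == pytest.approx(
            rep_c["max_spread_um"], rel=0.02
        )


class TestSpreadMetric:
    def test_gaussian_fwhm_is_2_355_sigma(self):
        x = np.linspace(-10, 10, 2001)
        for s in (0.5, 1.3):
            prof = np.exp(-(x**2) / (2 * s * s))
            assert profile_fwhm(x, prof) == pytest.approx(2.3548 * s, rel=1e-3)

    def test_fwhm_invariant_under_amplitude_scaling(self):
        x = np.linspace(-5, 5, 1001)
        prof = np.exp(-(x**2))
        assert profile_fwhm(x, 7.3 * prof) == pytest.approx(
            profile_fwhm(x, prof), rel=1e-12
        )

    def test_all_zero_profile_reported_missing(self):
        x = np.linspace(0, 1, 11)
        assert np.isnan(profile_fwhm(x, np.zeros_like(x)))
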