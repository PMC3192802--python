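"""Mass-action buffers, Hill pumps, spine sinks and the NMDA source."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dendrocrowd.calcium import (
    CALCINEURIN,
    CALMODULIN,
    NCX,
    PMCA,
    BufferSpec,
    SynapseSpec,
    buffer_equilibrium,
    buffer_rhs,
    nmda_current,
    nmda_particle_flux,
    pump_flux,
    spine_sink_rate,
)
from dendrocrowd.units import concentration_to_linear_density, current_to_ion_rate

S = 0.785  # μm², standard cross-section


class TestBuffers:
    def test_occupancy_derivatives_sum_to_zero(self):
        u_ca = np.array([100.0, 50.0])
        u_b = np.tile(
            concentration_to_linear_density(25.0, S) / 5.0, (5, 2)
        )
        du_ca, du_b = buffer_rhs(u_ca, u_b, CALMODULIN, S)
        np.testing.assert_allclose(du_b.sum(axis=0), 0.0, atol=1e-9)
        # calcium lost equals calcium bound
        occ = np.arange(5)[:, None]
        np.testing.assert_allclose(du_ca, -(du_b * occ).sum(axis=0), rtol=1e-12)

    def test_zero_calcium_drives_occupancy_down(self):
        u_b = np.vstack([np.full(3, 10.0)] * 2)
        du_ca, du_b = buffer_rhs(np.zeros(3), u_b, CALCINEURIN, S)
        assert np.all(du_b[1] < 0)  # bound state empties
        assert np.all(du_b[0] > 0)
        assert np.all(du_ca > 0)  # released calcium

    def test_calcineurin_equilibrium_ratio_is_kf_over_kb_times_ca(self):
        """Fixed point of the single-site ladder: bound/free = (50/25)·[Ca]."""
        for c in (0.1, 0.5, 2.0):
            occ = buffer_equilibrium(CALCINEURIN, c)
            assert occ[1] / occ[0] == pytest.approx(2.0 * c, rel=1e-12)

    def test_four_site_equilibrium_closed_form_vs_ode_integration(self):
        """Detailed balance of the macroscopic ladder: p_j ∝ Π (k_f,i c / k_b,i),
        cross-checked by long ODE integration at clamped calcium."""
        buf = BufferSpec("uniform", (100.0,) * 4, (50.0,) * 4, 10.0)
        c = 1.5
        x = (100.0 / 50.0) * c  # equal macroscopic pairs → geometric weights
        expected = x ** np.arange(5)
        expected = expected / expected.sum()
        np.testing.assert_allclose(buffer_equilibrium(buf, c), expected, rtol=1e-10)

        # ODE oracle at clamped calcium
        u_ca = concentration_to_linear_density(c, S)
        u_tot = concentration_to_linear_density(10.0, S)

        def rhs(t, y):
            _, du_b = buffer_rhs(np.array([u_ca]), y.reshape(5, 1), buf, S)
            return du_b.ravel()

        y0 = np.zeros(5)
        y0[0] = u_tot
        sol = solve_ivp(rhs, (0, 5.0), y0, method="LSODA", rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(sol.y[:, -1] / u_tot, expected, rtol=1e-5)

    def test_statistical_rates_give_binomial_occupancy(self):
        """When the macroscopic rates carry the statistical factors of n
        independent identical sites — k_f,j = (n−j+1)·k_on, k_b,j = j·k_off —
        detailed balance yields Binomial(n, p) occupancy."""
        n, k_on, k_off, c = 4, 100.0, 50.0, 1.5
        buf = BufferSpec(
            "independent-sites",
            tuple((n - j) * k_on for j in range(n)),
            tuple((j + 1) * k_off for j in range(n)),
            10.0,
        )
        p = (k_on / k_off) * c / (1.0 + (k_on / k_off) * c)
        from scipy.stats import binom

        expected = binom.pmf(np.arange(n + 1), n, p)
        np.testing.assert_allclose(buffer_equilibrium(buf, c), expected, rtol=1e-10)


class TestPumps:
    def test_half_saturation_at_K_half(self):
        u = concentration_to_linear_density(PMCA.K_half, S)
        sat = PMCA.rate_per_pump * PMCA.surface_density * math.pi
        assert pump_flux(u, PMCA, math.pi, S) == pytest.approx(0.5 * sat, rel=1e-12)

    def test_zero_calcium_no_flux_and_saturation_at_high_calcium(self):
        assert pump_flux(0.0, NCX, math.pi, S) == 0.0
        u_huge = concentration_to_linear_density(1e4 * NCX.K_half, S)
        sat = NCX.rate_per_pump * NCX.surface_density * math.pi
        assert pump_flux(u_huge, NCX, math.pi, S) == pytest.approx(sat, rel=1e-3)

    def test_ncx_hill_coefficient_shapes_the_activation(self):
        """Flux ratio at 2K vs K equals (2^1.7/(1+2^1.7)) / (1/2)."""
        u1 = concentration_to_linear_density(NCX.K_half, S)
        u2 = concentration_to_linear_density(2 * NCX.K_half, S)
        ratio = pump_flux(u2, NCX, math.pi, S) / pump_flux(u1, NCX, math.pi, S)
        expected = (2**1.7 / (1 + 2**1.7)) / 0.5
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_hill_coefficient_band_enforced(self):
        with pytest.raises(ValueError, match="hill"):
            PMCA.__class__(name="bad", rate_per_pump=1.0, surface_density=1.0,
                           K_half=1.0, hill=5.0)


class TestSpineSink:
    def test_rate_linear_in_neck_radius(self):
        r = spine_sink_rate(0.1, 0.246, 20.0)
        assert spine_sink_rate(0.2, 0.246, 20.0) == pytest.approx(2 * r)

    def test_rate_is_inverse_escape_time(self):
        from dendrocrowd.reduced import mfpt_escape_3d

        assert spine_sink_rate(0.1, 0.246, 20.0) == pytest.approx(
            1.0 / mfpt_escape_3d(0.246, 0.1, 20.0), rel=1e-14
        )

    def test_neck_wider_than_dendrite_rejected(self):
        with pytest.raises(ValueError):
            spine_sink_rate(0.6, 0.246, 20.0, dendrite_radius=0.5)


class TestNMDA:
    def test_zero_before_stimulus_onset(self):
        syn = SynapseSpec(position=10.0, t0=0.1)
        t = np.linspace(0.0, 0.099, 10)
        np.testing.assert_array_equal(nmda_current(t, syn), 0.0)

    def test_single_pulse_time_to_peak_closed_form(self):
        """τr·τd/(τd−τr)·ln(τd/τr) ≈ 10.2 ms for τr = 3 ms, τd = 80 ms."""
        syn = SynapseSpec(position=10.0, n_pulses=1, frequency=1.0)
        assert syn.time_to_peak == pytest.approx(10.2e-3, abs=0.1e-3)
        t = np.linspace(0.0, 0.05, 20001)
        cur = nmda_current(t, syn)
        assert t[np.argmax(cur)] == pytest.approx(syn.time_to_peak, abs=1e-4)
        assert cur.max() == pytest.approx(syn.peak_current, rel=1e-6)

    def test_charge_to_ion_bookkeeping(self):
        """Ions over one pulse = f_Ca · ∫I dt / (2e), by quadrature."""
        syn = SynapseSpec(position=10.0, n_pulses=1, frequency=1.0,
                          saturating=False)
        t = np.linspace(0.0, 3.0, 300_001)
        ions_rate = current_to_ion_rate(1.0, syn.ca_fraction) * nmda_current(t, syn)
        total_ions = np.trapezoid(ions_rate, t)
        # analytic: amp·(τd − τr), converted
        ttp = syn.time_to_peak
        gmax = math.exp(-ttp / syn.tau_decay) - math.exp(-ttp / syn.tau_rise)
        charge_pC = syn.peak_current / gmax * (syn.tau_decay - syn.tau_rise)
        expected = current_to_ion_rate(charge_pC, syn.ca_fraction)
        assert total_ions == pytest.approx(expected, rel=1e-4)

    def test_train_caps_at_single_channel_current(self):
        syn = SynapseSpec(position=10.0, n_pulses=100, frequency=100.0)
        t = np.linspace(0.0, 1.0, 5001)
        assert nmda_current(t, syn).max() <= syn.peak_current + 1e-9
        free = SynapseSpec(position=10.0, n_pulses=100, frequency=100.0,
                           saturating=False)
        assert nmda_current(t, free).max() > 5 * syn.peak_current

    def test_particle_flux_footprint_conserves_injection(self):
        syn = SynapseSpec(position=10.0, n_pulses=1, frequency=1.0)
        x = np.arange(0.0, 20.0001, 0.05)
        flux = nmda_particle_flux(0.01, syn, x)
        total = flux.sum() * 0.05
        expected = current_to_ion_rate(
            float(nmda_current(0.01, syn)), syn.ca_fraction
        )
        assert total == pytest.approx(expected, rel=1e-12)
        # footprint is local: half-width 0.025 μm around the receptor
        assert np.all(flux[np.abs(x - 10.0) > 0.1] == 0.0)

    def test_rise_must_be_faster_than_decay(self):
        with pytest.raises(ValueError):
            SynapseSpec(position=1.0, tau_rise=0.1, tau_decay=0.05)
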