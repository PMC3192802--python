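"""Compartment-chain ODEs, the reduced 1D PDE, and their mutual limit."""

import numpy as np
import pytest

from dendrocrowd.reduced import (
    CompartmentChainState,
    CompartmentSpec,
    InhomogeneousProfile,
    calibrate_geometry,
    drift_and_diffusion_coefficients,
    effective_diffusion_constant,
    solve_compartment_chain,
    solve_reduced_1d,
)


@pytest.fixture(scope="module")
def spec():
    return calibrate_geometry(0.05, 0.5, D=400.0)


class TestChain:
    def test_requires_three_compartments(self, spec):
        with pytest.raises(ValueError, match="at least 3"):
            solve_compartment_chain(
                CompartmentChainState(np.ones(2)), spec, 1.0
            )

    def test_total_count_conserved_with_reflecting_ends(self, spec):
        state0 = CompartmentChainState(np.r_[np.zeros(10), 1000.0, np.zeros(10)])
        traj = solve_compartment_chain(state0, spec, 0.5, bc="reflecting")
        np.testing.assert_allclose(traj.totals, 1000.0, rtol=1e-9)

    def test_symmetric_chain_relaxes_to_uniform(self, spec):
        m = 11
        state0 = CompartmentChainState(np.r_[np.zeros(5), 110.0, np.zeros(5)])
        # several relaxation times of the slowest mode
        t_relax = spec.hop_time * m**2
        traj = solve_compartment_chain(state0, spec, 5.0 * t_relax)
        np.testing.assert_allclose(traj.counts[-1], 10.0, rtol=1e-3)

    def test_absorbing_ends_lose_mass_monotonically(self, spec):
        state0 = CompartmentChainState(np.full(9, 10.0))
        traj = solve_compartment_chain(state0, spec, 1.0, bc="absorbing")
        totals = traj.totals
        assert totals[-1] < totals[0]
        assert np.all(np.diff(totals) <= 1e-9)

    def test_chain_converges_to_pde_gaussian_spreading(self, spec):
        """M = 200 compartments against the PDE on the same physical line."""
        m = 200
        x = (np.arange(m) + 0.5) * spec.L
        length = m * spec.L
        sigma0 = 8.0 * spec.L
        c0 = np.exp(-((x - length / 2) ** 2) / (2 * sigma0**2))
        state0 = CompartmentChainState(c0 * spec.L)
        t_end = 0.4
        traj = solve_compartment_chain(state0, spec, t_end, n_save=5)
        pde = solve_reduced_1d(c0, x, traj.times, spec=spec, bc="reflecting")
        chain_conc = traj.counts / spec.L
        num = np.sqrt(((chain_conc[-1] - pde.values[-1]) ** 2).sum())
        den = np.sqrt((pde.values[-1] ** 2).sum())
        assert num / den < 0.01


class TestReduced1D:
    def test_gaussian_variance_grows_at_2_D_eff_t(self):
        x = np.linspace(0.0, 20.0, 401)
        c0 = np.exp(-((x - 10.0) ** 2) / (2 * 0.2**2))
        t = np.array([0.0, 0.01])
        rec = solve_reduced_1d(c0, x, t, D=20.0)
        var = [
            (v * (x - 10.0) ** 2).sum() / v.sum() for v in rec.values
        ]
        # σ = sqrt(2·20·0.01) = 0.632 μm on top of the initial width
        assert var[1] - var[0] == pytest.approx(2 * 20.0 * 0.01, rel=1e-3)
        assert np.sqrt(2 * 20.0 * 0.01) == pytest.approx(0.632, abs=1e-3)

    def test_zero_stays_zero_and_mass_conserved(self):
        x = np.linspace(0.0, 10.0, 201)
        t = np.linspace(0.0, 0.05, 6)
        zero = solve_reduced_1d(np.zeros_like(x), x, t, D=20.0)
        assert np.all(zero.values == 0.0)
        c0 = np.exp(-((x - 5.0) ** 2))
        rec = solve_reduced_1d(c0, x, t, D=20.0, bc="reflecting")
        np.testing.assert_allclose(
            rec.values.sum(axis=1), c0.sum(), rtol=1e-9
        )
        assert rec.values.min() >= -1e-12

    def test_negative_initial_condition_rejected(self):
        x = np.linspace(0.0, 1.0, 11)
        with pytest.raises(ValueError):
            solve_reduced_1d(-np.ones_like(x), x, [0.0, 0.1], D=1.0)

    def test_crowded_transient_is_time_rescaled_aqueous_transient(self):
        """D and D/20 solutions map onto each other under t → 20 t."""
        x = np.linspace(0.0, 20.0, 401)
        c0 = np.exp(-((x - 10.0) ** 2) / 0.5)
        t_fast = np.array([0.0, 0.5e-3, 1e-3, 2e-3])
        fast = solve_reduced_1d(c0, x, t_fast, D=400.0)
        slow = solve_reduced_1d(c0, x, 20.0 * t_fast, D=20.0)
        np.testing.assert_allclose(slow.values, fast.values, atol=1e-8)

    def test_absorbing_boundary_drains_mass(self):
        x = np.linspace(0.0, 10.0, 201)
        c0 = np.exp(-((x - 2.0) ** 2))
        rec = solve_reduced_1d(c0, x, np.linspace(0, 0.2, 5), D=20.0, bc="mixed")
        masses = rec.values.sum(axis=1)
        assert np.all(np.diff(masses) < 0)
        assert masses[-1] < 0.7 * masses[0]


class TestDriftDiffusion:
    def test_constant_opening_gives_zero_drift_and_D_eff(self, spec):
        profile = InhomogeneousProfile(
            eps_of_x=lambda x: spec.eps,
            V_of_x=lambda x: spec.volume,  # compartment volume S·L
            domain=(0.0, 20.0),
        )
        a_of_x, b_of_x = drift_and_diffusion_coefficients(profile, spec)
        xs = np.linspace(0.5, 19.5, 7)
        np.testing.assert_allclose(a_of_x(xs), 0.0, atol=1e-8)
        np.testing.assert_allclose(
            b_of_x(xs), effective_diffusion_constant(spec), rtol=1e-6
        )

    def test_drift_sign_matches_opening_gradient(self, spec):
        """Openings widening to the right pull the ensemble rightward; the
        1D Euler–Maruyama oracle confirms the direction."""
        grad = 0.002
        profile = InhomogeneousProfile(
            eps_of_x=lambda x: spec.eps + grad * (x - 10.0),
            V_of_x=lambda x: spec.volume,
            domain=(0.0, 20.0),
        )
        a_of_x, b_of_x = drift_and_diffusion_coefficients(profile, spec)
        xs = np.linspace(2.0, 18.0, 9)
        assert np.all(np.sign(a_of_x(xs)) == 1.0)

        rng = np.random.default_rng(11)
        n, dt, nsteps = 4000, 1e-4, 500
        pos = np.full(n, 10.0)
        for _ in range(nsteps):
            pos += a_of_x(pos) * dt + np.sqrt(2 * b_of_x(pos) * dt) * rng.normal(size=n)
        drift_mc = pos.mean() - 10.0
        predicted = a_of_x(10.0) * dt * nsteps
        assert drift_mc > 0
        assert drift_mc == pytest.approx(predicted, rel=0.5)

    def test_pde_with_gradient_profile_shifts_center_of_mass(self, spec):
        grad = 0.002
        profile = InhomogeneousProfile(
            eps_of_x=lambda x: spec.eps + grad * (x - 10.0),
            V_of_x=lambda x: spec.volume,
            domain=(0.0, 20.0),
        )
        x = np.linspace(0.0, 20.0, 401)
        c0 = np.exp(-((x - 10.0) ** 2) / 0.5)
        rec = solve_reduced_1d(c0, x, [0.0, 0.05], spec=spec, profile=profile)
        com0 = (rec.values[0] * x).sum() / rec.values[0].sum()
        com1 = (rec.values[-1] * x).sum() / rec.values[-1].sum()
        assert com1 > com0
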