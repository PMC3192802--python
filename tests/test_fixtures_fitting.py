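"""Synthetic uncaging fixtures and the diffusion-constant fitter."""

import numpy as np
import pytest

from dendrocrowd.fixtures import UncagingFixtureSpec, generate_fixture
from dendrocrowd.fitting import fit_diffusion_constant
from dendrocrowd.reduced.pde1d import solve_reduced_1d


def _fit_kwargs(spec, **extra):
    return dict(
        spot_center=spec.spot_center,
        spot_width=spec.spot_width,
        domain_length=spec.domain_length,
        **extra,
    )


class TestGenerator:
    def test_noise_free_single_replicate_equals_solver_output(self):
        spec = UncagingFixtureSpec(noise_sd=0.0, replicates=1, duration=0.01)
        rec, sidecar = generate_fixture(spec, 100.0)
        x = np.arange(0.0, spec.domain_length + spec.dx / 2, spec.dx)
        c0 = np.exp(-((x - spec.spot_center) ** 2) / (2 * spec.spot_width**2))
        sol = solve_reduced_1d(c0, x, spec.times, D=100.0)
        for i in (0, len(spec.times) // 2, -1):
            expected = np.interp(spec.positions, x, sol.values[i])
            np.testing.assert_allclose(rec.values[i], expected, rtol=1e-12)
        assert sidecar["truth_D"] == 100.0
        assert "truth_D" not in rec.meta  # truth never leaks into the record

    def test_acquisition_grid_follows_line_scan_conventions(self):
        spec = UncagingFixtureSpec()
        assert np.diff(spec.positions) == pytest.approx(0.6)
        assert np.diff(spec.times) == pytest.approx(0.7e-3)

    def test_replicate_averaging_reduces_noise_by_sqrt_n(self):
        ref = UncagingFixtureSpec(noise_sd=0.1, replicates=1, rng_seed=1)
        avg = UncagingFixtureSpec(noise_sd=0.1, replicates=4, rng_seed=1)
        clean = UncagingFixtureSpec(noise_sd=0.0, replicates=1)
        rec1, _ = generate_fixture(ref, 50.0)
        rec4, _ = generate_fixture(avg, 50.0)
        rec0, _ = generate_fixture(clean, 50.0)
        sd1 = (rec1.values - rec0.values).std()
        sd4 = (rec4.values - rec0.values).std()
        assert sd1 / sd4 == pytest.approx(2.0, rel=0.15)

    def test_seeded_determinism(self):
        a, _ = generate_fixture(UncagingFixtureSpec(rng_seed=9), 30.0)
        b, _ = generate_fixture(UncagingFixtureSpec(rng_seed=9), 30.0)
        np.testing.assert_array_equal(a.values, b.values)


class TestFitter:
    def test_inverse_crime_noise_free_recovery(self):
        spec = UncagingFixtureSpec(noise_sd=0.0, replicates=1)
        rec, _ = generate_fixture(spec, 400.0)
        res = fit_diffusion_constant(rec, **_fit_kwargs(spec, n_boot=3))
        assert res.D_hat == pytest.approx(400.0, rel=0.02)

    @pytest.mark.parametrize("truth", [20.0, 27.0, 400.0])
    def test_recovery_across_the_three_regimes(self, truth):
        """Crowded, near-spine and aqueous regimes recovered within 10%."""
        spec = UncagingFixtureSpec(rng_seed=17, noise_sd=0.03)
        rec, _ = generate_fixture(spec, truth)
        res = fit_diffusion_constant(rec, **_fit_kwargs(spec, n_boot=3))
        assert res.D_hat == pytest.approx(truth, rel=0.10)

    def test_crowded_to_aqueous_fitted_ratio_is_one_twentieth(self):
        spec_c = UncagingFixtureSpec(rng_seed=5, noise_sd=0.02)
        spec_a = UncagingFixtureSpec(rng_seed=6, noise_sd=0.02)
        rec_c, _ = generate_fixture(spec_c, 20.0)
        rec_a, _ = generate_fixture(spec_a, 400.0)
        fit_c = fit_diffusion_constant(rec_c, **_fit_kwargs(spec_c, n_boot=10))
        fit_a = fit_diffusion_constant(rec_a, **_fit_kwargs(spec_a, n_boot=10))
        ratio = fit_c.D_hat / fit_a.D_hat
        lo = fit_c.ci[0] / fit_a.ci[1]
        hi = fit_c.ci[1] / fit_a.ci[0]
        assert lo <= 1.0 / 20.0 <= hi
        assert ratio == pytest.approx(0.05, rel=0.1)

    def test_parameter_recovery_over_twenty_seeds(self):
        """Round trip generate → fit within 10% for noise_sd ≤ 0.05."""
        errors = []
        for seed in range(20):
            spec = UncagingFixtureSpec(rng_seed=seed, noise_sd=0.05, duration=0.03)
            rec, _ = generate_fixture(spec, 20.0)
            res = fit_diffusion_constant(rec, **_fit_kwargs(spec, n_boot=0))
            errors.append(abs(res.D_hat - 20.0) / 20.0)
        assert max(errors) <= 0.10

    def test_brownian_generated_record_recovers_effective_D(
        self, calibrated_trajectory, calibrated_spec
    ):
        """Cross-simulator loop: fit the 3D Brownian line scan with the 1D
        forward model; the result must be consistent with D_eff."""
        from dendrocrowd.brownian import record_linescan
        from dendrocrowd.reduced import effective_diffusion_constant

        rec = record_linescan(calibrated_trajectory, normalize=False)
        res = fit_diffusion_constant(
            rec, init="first-frame", domain_length=20.0, n_boot=10,
            per_location_norm=False,
        )
        d_eff = effective_diffusion_constant(calibrated_spec)
        assert res.D_hat == pytest.approx(d_eff, rel=0.10)

    def test_needs_at_least_two_locations(self):
        spec = UncagingFixtureSpec(noise_sd=0.0, replicates=1)
        rec, _ = generate_fixture(spec, 100.0)
        from dendrocrowd.linescan import LineScanRecord

        single = LineScanRecord(
            rec.times, rec.positions[:1], rec.values[:, :1], rec.meta
        )
        with pytest.raises(ValueError, match="two read-out locations"):
            fit_diffusion_constant(single)
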