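"""Density-conservation regression, tension and concentration conversions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropsf.densitometry import (
    DensityFitResult,
    SampleRecord,
    dense_phase_concentration,
    density_from_volume_fraction,
    fit_density_line,
    surface_tension,
    synthesize_density_batch,
    volume_fraction_from_concentration,
)


class TestDensityLine:
    def test_zero_noise_exact_recovery(self):
        recs = synthesize_density_batch(97.0, 1000.2, n=13, noise_sd=0.0, seed=4)
        fit = fit_density_line(recs)
        assert fit.delta_rho == pytest.approx(97.0, rel=1e-10)
        assert fit.rho_alpha == pytest.approx(1000.2, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_simulated_recovery_within_two_sds(self):
        """Over 200 seeded batches (n=13, ratio noise 5e-4) the reported
        2-sd interval covers the true delta_rho at least 90% of the time."""
        hits = 0
        for seed in range(200):
            recs = synthesize_density_batch(97.0, 1000.2, n=13, noise_sd=5e-4,
                                            seed=seed)
            fit = fit_density_line(recs)
            if abs(fit.delta_rho - 97.0) <= 2 * fit.delta_rho_sd:
                hits += 1
        assert hits >= 180

    def test_non_positive_slope_rejected(self):
        recs = [SampleRecord(1000.0 + i, 80.0, 8.0 - i) for i in range(4)]
        with pytest.raises(ValueError, match="denser"):
            fit_density_line(recs)

    def test_needs_three_spanning_records(self):
        with pytest.raises(ValueError):
            fit_density_line([SampleRecord(1000.0, 80.0, 1.0)] * 2)

    def test_same_seed_determinism(self):
        a = synthesize_density_batch(97.0, 1000.2, seed=9)
        b = synthesize_density_batch(97.0, 1000.2, seed=9)
        assert all(x.sample_density == y.sample_density for x, y in zip(a, b))

    def test_range_below_rho_alpha_rejected(self):
        with pytest.raises(ValueError):
            synthesize_density_batch(97.0, 1000.2, rho0_range=(990.0, 999.0))


class TestSurfaceTension:
    def test_condensate_scale_values(self):
        assert surface_tension(97.0, 293.0).gamma == pytest.approx(82, abs=0.5)
        assert surface_tension(69.0, 237.0).gamma == pytest.approx(38, abs=0.5)

    def test_zero_input_sds_give_zero_gamma_sd(self):
        assert surface_tension(97.0, 293.0, 0.0, 0.0).gamma_sd == 0.0

    @settings(max_examples=25, derandomize=True)
    @given(drho=st.floats(10.0, 300.0), lc=st.floats(50.0, 500.0),
           k=st.floats(0.2, 5.0))
    def test_quadratic_homogeneity_in_lc(self, drho, lc, k):
        g1 = surface_tension(drho, lc).gamma
        g2 = surface_tension(drho, k * lc).gamma
        assert g2 == pytest.approx(k**2 * g1, rel=1e-9)

    def test_uncertainty_propagation(self):
        t = surface_tension(100.0, 300.0, 10.0, 6.0)
        rel = np.sqrt(0.1**2 + (2 * 6 / 300) ** 2)
        assert t.gamma_sd == pytest.approx(t.gamma * rel, rel=1e-12)


class TestConversions:
    def test_solvent_limit(self, proteins):
        rho = density_from_volume_fraction(0.0, proteins["ddx4n_1-229"])
        assert rho == pytest.approx(998.2)

    def test_pure_protein_limit(self, proteins):
        rho = density_from_volume_fraction(1.0, proteins["ddx4n_1-229"])
        assert rho == pytest.approx(25109.54 / 19020.3 * 1000, rel=1e-12)

    def test_linear_in_phi(self, proteins):
        spec = proteins["ddx4n_1-229"]
        mid = density_from_volume_fraction(0.5, spec)
        ends = (density_from_volume_fraction(0.0, spec)
                + density_from_volume_fraction(1.0, spec)) / 2
        assert mid == pytest.approx(ends, rel=1e-12)

    def test_phi_from_concentration(self, proteins):
        spec = proteins["ddx4n_1-229"]
        assert volume_fraction_from_concentration(32e-6, spec) == pytest.approx(
            6.09e-4, abs=5e-7)
        assert volume_fraction_from_concentration(0.0, spec) == 0.0
        assert volume_fraction_from_concentration(15.9e-3, spec) == pytest.approx(
            0.302, abs=1e-3)

    def test_unphysical_phi_rejected(self, proteins):
        with pytest.raises(ValueError, match="unphysical"):
            volume_fraction_from_concentration(1.0, proteins["ddx4n_1-229"])

    def test_roundtrip_density_concentration_is_linear(self, proteins):
        spec = proteins["ddx4n_1-229"]
        cs = np.array([1e-4, 2e-4, 4e-4])
        rhos = [density_from_volume_fraction(
            volume_fraction_from_concentration(c, spec), spec) for c in cs]
        slopes = np.diff(rhos) / np.diff(cs)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)


class TestDensePhase:
    def test_construct_concentrations(self, proteins):
        f229 = DensityFitResult(97.0, 10.0, 1000.2, 1.0, 1.0)
        c = dense_phase_concentration(f229, proteins["ddx4n_1-229"], 32e-6)
        assert c * 1e3 == pytest.approx(15.9, abs=0.05)
        f231 = DensityFitResult(69.0, 5.0, 1000.2, 1.0, 1.0)
        c = dense_phase_concentration(f231, proteins["ddx4n_1-231"], 54e-6)
        assert 11.2 <= c * 1e3 <= 11.3

    def test_zero_contrast_returns_c_alpha(self, proteins):
        f = DensityFitResult(0.0, 0.0, 1000.2, 0.0, 1.0)
        c = dense_phase_concentration(f, proteins["ddx4n_1-229"], 32e-6)
        assert c == pytest.approx(32e-6, rel=1e-12)
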