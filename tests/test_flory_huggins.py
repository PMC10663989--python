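"""Flory-Huggins free energy, critical point, binodal and curvature shift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dropsf.constants import BOLTZMANN, ROOM_TEMPERATURE_K
from dropsf.flory_huggins import (
    BinodalPoint,
    CurvatureParams,
    FHModel,
    SinglePhaseError,
    critical_point,
    curvature_shifted_dilute_branch,
    extract_chi,
    free_energy_density,
    laplace_pressure,
    mu_polymer,
    mu_solvent,
    solve_binodal,
)


class TestFreeEnergy:
    def test_symmetric_ideal_mixing(self):
        assert free_energy_density(0.5, FHModel(1, 0.0)) == pytest.approx(
            np.log(0.5), rel=1e-12)

    def test_symmetry_for_monomers(self):
        m = FHModel(1, 1.3)
        phis = np.linspace(0.05, 0.95, 19)
        assert np.allclose(free_energy_density(phis, m),
                           free_energy_density(1 - phis, m))

    def test_second_derivative_vanishes_at_critical_point(self):
        n = 234
        phi_c, chi_c = critical_point(n)
        m = FHModel(n, chi_c)
        eps = 1e-5
        f2 = (free_energy_density(phi_c + eps, m) - 2 * free_energy_density(phi_c, m)
              + free_energy_density(phi_c - eps, m)) / eps**2
        assert abs(f2) < 1e-4


class TestCriticalPoint:
    def test_symmetric_blend(self):
        assert critical_point(1) == (0.5, 2.0)

    def test_closed_form_n100(self):
        phi_c, _ = critical_point(100)
        assert phi_c == pytest.approx(1 / 11, rel=1e-12)


class TestBinodal:
    def test_residuals_at_solution(self):
        for n, chi in [(234, 0.641), (236, 0.616), (50, 0.70), (1, 2.5)]:
            b = solve_binodal(FHModel(n, chi))
            assert abs(mu_solvent(b.phi_alpha, n, chi)
                       - mu_solvent(b.phi_beta, n, chi)) < 1e-10
            assert abs(mu_polymer(b.phi_alpha, n, chi)
                       - mu_polymer(b.phi_beta, n, chi)) < 1e-10

    def test_monomer_symmetry_and_bisection_oracle(self):
        b = solve_binodal(FHModel(1, 2.5))
        assert b.phi_alpha + b.phi_beta == pytest.approx(1.0, abs=1e-12)
        # independent oracle: ln((1-phi)/phi) = chi (1 - 2 phi)
        phi = brentq(lambda p: np.log((1 - p) / p) - 2.5 * (1 - 2 * p), 1e-6, 0.49)
        assert b.phi_alpha == pytest.approx(phi, rel=1e-10)

    def test_near_critical_closure(self):
        for n in (1, 234):
            phi_c, chi_c = critical_point(n)
            b = solve_binodal(FHModel(n, chi_c * (1 + 1e-6)))
            assert b.phi_alpha == pytest.approx(phi_c, rel=0.05)
            assert b.phi_beta == pytest.approx(phi_c, rel=0.05)

    def test_subcritical_rejected(self):
        with pytest.raises(SinglePhaseError):
            solve_binodal(FHModel(234, 0.5))

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(n=st.integers(2, 400), excess=st.floats(0.01, 0.8))
    def test_branches_move_apart_with_chi(self, n, excess):
        _, chi_c = critical_point(n)
        b1 = solve_binodal(FHModel(n, chi_c * (1 + excess)))
        b2 = solve_binodal(FHModel(n, chi_c * (1 + excess + 0.05)))
        assert b2.phi_alpha < b1.phi_alpha
        assert b2.phi_beta > b1.phi_beta


class TestExtractChi:
    @pytest.mark.parametrize("mode", ["match_dilute", "match_dense", "match_gap", "joint"])
    def test_roundtrip(self, mode):
        chi_true = 0.62
        b = solve_binodal(FHModel(234, chi_true))
        assert extract_chi(b, 234, mode) == pytest.approx(chi_true, abs=1e-6)

    def test_unattainable_observable(self):
        with pytest.raises(ValueError, match="attainable"):
            extract_chi(BinodalPoint(0.9, 0.99), 234, "match_dilute",
                        bracket_scale=1.05)


class TestCurvature:
    def test_laplace_pressure_worked_example(self):
        assert laplace_pressure(100e-6, 200e-6) == pytest.approx(1.0, rel=1e-12)
        assert laplace_pressure(38e-6, 200e-6) == pytest.approx(0.38, rel=1e-12)

    def test_vanishes_for_large_drops(self):
        assert laplace_pressure(100e-6, 1e6) < 1e-9

    def test_zero_offset_reproduces_binodal(self):
        m = FHModel(234, 0.641)
        assert solve_binodal(m, dmu_p_beta=0.0).phi_alpha == solve_binodal(m).phi_alpha

    def test_shift_is_positive_and_tiny(self):
        m = FHModel(234, 0.641)
        base = solve_binodal(m).phi_alpha
        shifted = curvature_shifted_dilute_branch(
            m, CurvatureParams(200e-6, 100e-6, 31.6))
        rel = shifted / base - 1
        assert rel > 0
        assert rel < 1e-5  # "less than 1e-3 percent"

    def test_shift_matches_linearized_chemical_potential_balance(self):
        m = FHModel(234, 0.641)
        curv = CurvatureParams(200e-6, 100e-6, 31.6)
        base = solve_binodal(m).phi_alpha
        shifted = curvature_shifted_dilute_branch(m, curv)
        expected = (curv.molecular_volume * 1e-27 * laplace_pressure(curv.gamma, curv.radius)
                    / (BOLTZMANN * ROOM_TEMPERATURE_K))
        # dilute branch is near-ideal, so d(ln phi_alpha) ~ v_p dP / kT
        assert shifted / base - 1 == pytest.approx(expected, rel=0.05)
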