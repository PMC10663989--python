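"""Lattice SCF solver: conservation laws, bulk consistency, widths, sweeps."""

import numpy as np
import pytest
from dataclasses import replace

from dropsf._scf_kernels import scf_map
from dropsf.flory_huggins import FHModel, critical_point, solve_binodal
from dropsf.scf import (
    SCFConfig,
    SCFProfile,
    continuation_sweep,
    end_segment_profile,
    fit_interface_width,
    rank_profiles,
    solve_scf,
    surface_tension_from_profile,
    width_maps,
)

from conftest import at_chi


class TestSolver:
    def test_subcritical_uniform_stays_flat(self):
        cfg = SCFConfig(chain_length=100, chi=0.50,
                        init_profile=np.full(200, 0.06))
        prof = solve_scf(cfg)
        assert prof.converged
        assert np.abs(prof.phi_p - 0.06).max() < 1e-8

    def test_incompressibility_and_conservation(self, scf_229):
        prof = scf_229.profile
        assert np.abs(prof.phi_p + prof.phi_solvent - 1.0).max() < 1e-12
        assert abs(prof.phi_p.sum() - 0.06 * 200) < 1e-8 * 12

    def test_plateaus_match_binodal(self, scf_229, scf_231):
        for res, (n, chi) in [(scf_229, (234, 0.641)), (scf_231, (236, 0.616))]:
            b = solve_binodal(FHModel(n, chi))
            phi = res.profile.phi_p
            lo, hi = sorted([phi[:3].mean(), phi[-3:].mean()])
            assert abs(lo - b.phi_alpha) < 1e-5
            assert abs(hi - b.phi_beta) < 1e-5

    def test_mirror_symmetry_fixed_point(self, scf_229):
        cfg = SCFConfig(chain_length=234, chi=0.641)
        prof = scf_229.profile
        flipped = prof.phi_p[::-1].copy()
        phi_new, _ = scf_map(flipped, 234, 0.641, 1 / 6, cfg.theta)
        assert np.abs(phi_new - flipped).max() < 10 * cfg.tolerance
        res_flipped = surface_tension_from_profile(
            SCFProfile(phi_p=flipped, field=prof.field[::-1].copy(),
                       phi_end=prof.phi_end[::-1].copy(), converged=True,
                       iterations=0, residual=prof.residual), cfg)
        assert res_flipped.gamma_lattice == pytest.approx(
            scf_229.gamma_lattice, abs=1e-10)

    def test_nonconvergence_is_flagged(self):
        cfg = SCFConfig(chain_length=234, chi=0.70, max_iterations=3)
        prof = solve_scf(cfg)
        assert not prof.converged


class TestSurfaceTension:
    def test_flat_profile_has_zero_gamma(self):
        cfg = SCFConfig(chain_length=100, chi=0.40,
                        init_profile=np.full(200, 0.06))
        res = surface_tension_from_profile(solve_scf(cfg), cfg)
        assert abs(res.gamma_lattice) < 1e-10

    def test_gamma_positive_increasing_and_vanishing_at_critical(self, sweep_234):
        conv = [r for r in sweep_234 if r.converged]
        chis = np.array([r.chi for r in conv])
        gams = np.array([r.gamma_lattice for r in conv])
        order = np.argsort(chis)
        gams = gams[order]
        assert np.all(gams >= -1e-12)
        assert np.all(np.diff(gams) > 0)  # dgamma/dchi > 0
        assert gams[0] < 0.02 * gams[-1]  # gamma -> 0 toward chi_c

    def test_chain_length_234_vs_236_curves_differ_below_one_percent(
            self, sweep_234, sweep_236):
        """Over the range spanning both measured interaction parameters the
        two gamma(chi) curves are within 1 percent of each other."""
        g234 = {round(r.chi, 6): r.gamma_si for r in sweep_234 if r.converged}
        g236 = {round(r.chi, 6): r.gamma_si for r in sweep_236 if r.converged}
        common = [c for c in g234 if c in g236 and 0.61 <= c <= 0.67]
        assert len(common) >= 8
        for c in common:
            assert abs(g234[c] / g236[c] - 1) < 0.01


class TestWidth:
    def test_exact_tanh_self_fit(self):
        cfg = SCFConfig(chain_length=234, chi=0.641)
        z = np.arange(1, 201) * 0.512
        w_true, z0, a, b = 3.3, 40.0, 0.15, 0.147
        phi = a - b * np.tanh(2 * (z - z0) / w_true)
        prof = SCFProfile(phi_p=phi, field=np.zeros(200), phi_end=phi,
                          converged=True, iterations=0, residual=0.0)
        fit = fit_interface_width(prof, cfg)
        assert fit.width == pytest.approx(w_true, abs=1e-8)
        assert fit.center == pytest.approx(z0, abs=1e-8)

    def test_width_decreases_with_chi(self, sweep_234):
        conv = sorted((r for r in sweep_234 if r.converged and r.width_fit),
                      key=lambda r: r.chi)
        widths = [r.width_fit.width for r in conv if r.chi > 0.60]
        assert np.all(np.diff(widths) < 0)


class TestEndSegments:
    def test_dilute_side_excess(self, scf_229):
        cfg = SCFConfig(chain_length=234, chi=0.641)
        allp, endp = end_segment_profile(cfg, scf_229.profile)
        # dilute side = where the all-segment profile is low
        dilute = allp < 0.25
        assert np.all(endp[dilute] >= allp[dilute] - 1e-12)
        assert np.max(endp[dilute] - allp[dilute]) > 1e-3  # strict enrichment

    def test_single_segment_chain_ends_equal_whole(self):
        cfg = SCFConfig(chain_length=1, chi=2.5, n_layers=60, mean_phi=0.3,
                        init_restrict_layers=10)
        prof = solve_scf(cfg)
        assert np.allclose(prof.phi_end, prof.phi_p, atol=1e-12)

    def test_rank_sum_identity(self, scf_229):
        cfg = SCFConfig(chain_length=234, chi=0.641)
        ranks = rank_profiles(scf_229.profile, cfg)
        assert np.abs(ranks.sum(axis=0) - scf_229.profile.phi_p).max() < 1e-9


class TestSweeps:
    def test_exact_extras_present(self, sweep_234, sweep_236):
        assert any(r.chi == 0.641 for r in sweep_234)
        assert any(r.chi == 0.616 for r in sweep_236)

    def test_single_interface_along_sweep(self, sweep_234):
        assert all(r.single_interface for r in sweep_234 if r.converged)

    def test_width_map_cell_matches_direct_sweep(self):
        df = width_maps([234], [0.68, 0.66])
        base = SCFConfig(chain_length=234, chi=0.68)
        direct = at_chi(continuation_sweep(base, chi_extra=[0.68],
                                           chi_stop=0.66 - 1e-9), 0.68)
        row = df[np.isclose(df.chi, 0.68)].iloc[0]
        assert row.gamma_uN_m == pytest.approx(direct.gamma_si, rel=1e-9)
        assert row.width_nm < df[np.isclose(df.chi, 0.66)].iloc[0].width_nm
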