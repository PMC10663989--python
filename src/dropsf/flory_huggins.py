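"""Flory-Huggins bulk thermodynamics for a polymer-solvent mixture.

Free energy per lattice site (units of kT), for chains of N segments at
volume fraction phi in a one-site solvent:

    f(phi) = (phi/N) ln phi + (1-phi) ln(1-phi) + chi phi (1-phi)

Coexistence (the binodal) equates the solvent chemical potential

    mu_s = ln(1-phi) + (1 - 1/N) phi + chi phi^2

and the per-chain polymer chemical potential

    mu_p = ln phi - (N-1)(1-phi) + chi N (1-phi)^2

between the dilute (alpha) and dense (beta) branches. The critical point is
phi_c = 1/(1+sqrt(N)), chi_c = (1+1/sqrt(N))^2 / 2.

The Laplace pressure of a curved droplet of the dense phase shifts the
equilibrium slightly: the pressure excess 2 gamma / R adds v_p dP to the
per-chain chemical potential inside the droplet, raising the dilute-branch
volume fraction by a relative factor of roughly v_p dP / kT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from dropsf.constants import BOLTZMANN, ROOM_TEMPERATURE_K

_XTOL = 1e-16
_RTOL = 8.881784197001252e-16  # 4 * eps, brentq's floor


@dataclass(frozen=True)
class FHModel:
    """Chain length N_p (solvent occupies one site) and interaction chi per kT."""

    chain_length: float
    chi: float

    def __post_init__(self) -> None:
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if not np.isfinite(self.chi):
            raise ValueError("chi must be finite")


@dataclass(frozen=True)
class BinodalPoint:
    """Coexisting polymer volume fractions outside (alpha) and inside (beta)."""

    phi_alpha: float
    phi_beta: float


@dataclass(frozen=True)
class CurvatureParams:
    """Droplet radius, surface tension, per-chain molecular volume, temperature.

    Units: radius m, gamma N/m, molecular_volume nm^3, temperature K."""

    radius: float
    gamma: float
    molecular_volume: float
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if min(self.radius, self.gamma, self.molecular_volume, self.temperature) <= 0:
            raise ValueError("all curvature parameters must be positive")


class SinglePhaseError(ValueError):
    """chi at or below the critical value: no two-phase coexistence."""


def free_energy_density(phi: float | np.ndarray, model: FHModel) -> float | np.ndarray:
    """Mixing free energy per site in kT, with x ln x -> 0 at the boundaries."""
    phi = np.asarray(phi, dtype=float)
    if np.any((phi < 0) | (phi > 1)):
        raise ValueError("phi must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        ent_p = np.where(phi > 0, phi * np.log(np.where(phi > 0, phi, 1.0)), 0.0)
        ent_s = np.where(phi < 1, (1 - phi) * np.log(np.where(phi < 1, 1 - phi, 1.0)), 0.0)
    out = ent_p / model.chain_length + ent_s + model.chi * phi * (1 - phi)
    return float(out) if out.ndim == 0 else out


def mu_solvent(phi, n, chi):
    return np.log1p(-phi) + (1.0 - 1.0 / n) * phi + chi * phi**2


def mu_polymer(phi, n, chi):
    """Per-chain polymer chemical potential (kT)."""
    return np.log(phi) - (n - 1.0) * (1.0 - phi) + chi * n * (1.0 - phi) ** 2


def critical_point(n: float) -> tuple[float, float]:
    """(phi_c, chi_c): simultaneous zeros of f'' and f'''."""
    if n < 1:
        raise ValueError("chain length must be >= 1")
    rn = np.sqrt(n)
    return 1.0 / (1.0 + rn), 0.5 * (1.0 + 1.0 / rn) ** 2


def spinodal(n: float, chi: float) -> tuple[float, float]:
    """Roots of f''(phi) = 1/(N phi) + 1/(1-phi) - 2 chi = 0."""
    phi_c, chi_c = critical_point(n)
    if chi <= chi_c:
        raise SinglePhaseError(f"chi = {chi} <= chi_c = {chi_c:.6f} (N = {n})")
    f2 = lambda p: 1.0 / (n * p) + 1.0 / (1.0 - p) - 2.0 * chi
    lo = brentq(f2, 1e-300, phi_c, xtol=1e-300, rtol=_RTOL)
    hi = brentq(f2, phi_c, 1 - 1e-15, xtol=_XTOL, rtol=_RTOL)
    return lo, hi


def solve_binodal(model: FHModel, dmu_p_beta: float = 0.0) -> BinodalPoint:
    """Coexisting volume fractions for chi > chi_c.

    Solves mu_s(alpha) = mu_s(beta) and mu_p(alpha) = mu_p(beta) + dmu_p_beta
    by a nested bracketed search: outside the spinodal both chemical
    potentials are monotone in phi, so for each candidate phi_alpha the
    matching phi_beta is a bracketed 1-D root, and the polymer-potential
    mismatch is itself monotone in ln phi_alpha. dmu_p_beta (kT per chain)
    is the curvature offset; 0 gives the flat-interface binodal.

    Residuals of both equalities at the returned point are at machine level
    (< 1e-10 in kT).
    """
    n, chi = model.chain_length, model.chi
    slo, shi = spinodal(n, chi)
    mu_s_shi = mu_solvent(shi, n, chi)

    def phi_beta_of(pa: float) -> float:
        target = mu_solvent(pa, n, chi)
        f = lambda pb: mu_solvent(pb, n, chi) - target
        return brentq(f, shi, 1.0 - 1e-14, xtol=_XTOL, rtol=_RTOL)

    def mismatch(log_pa: float) -> float:
        pa = np.exp(log_pa)
        pb = phi_beta_of(pa)
        return mu_polymer(pa, n, chi) - mu_polymer(pb, n, chi) - dmu_p_beta

    # the dilute branch can only pair with a dense partner while its solvent
    # potential stays below mu_s at the upper spinodal; pa_min marks that edge
    # (when mu_s(shi) >= 0 every dilute composition has a partner)
    hi = np.log(slo) - 1e-12
    if mu_s_shi < 0.0:
        pa_min = brentq(lambda p: mu_solvent(p, n, chi) - mu_s_shi,
                        1e-300, slo, xtol=1e-300, rtol=_RTOL)
        lo = min(np.log(pa_min) + 1e-9, hi - 1e-12)
    else:
        lo = hi - 80.0
    log_pa = brentq(mismatch, lo, hi, xtol=1e-15, rtol=_RTOL)
    pa = float(np.exp(log_pa))
    return BinodalPoint(phi_alpha=pa, phi_beta=float(phi_beta_of(pa)))


def laplace_pressure(gamma: float, radius: float) -> float:
    """Pressure excess 2 gamma / R inside a droplet, in Pa (gamma N/m, R m)."""
    if gamma <= 0 or radius <= 0:
        raise ValueError("gamma and radius must be positive")
    return 2.0 * gamma / radius


def curvature_shifted_dilute_branch(model: FHModel, curv: CurvatureParams) -> float:
    """Dilute-branch volume fraction with the Laplace-pressure offset.

    The droplet's internal pressure excess dP = 2 gamma / R augments the
    per-chain chemical potential of polymer in the dense phase by v_p dP.
    Coexistence is re-solved with that offset (in kT); the dilute branch
    rises by a relative amount close to v_p dP / kT.
    """
    dp = laplace_pressure(curv.gamma, curv.radius)
    offset = curv.molecular_volume * 1e-27 * dp / (BOLTZMANN * curv.temperature)
    return solve_binodal(model, dmu_p_beta=offset).phi_alpha


_CHI_MODES = ("match_dilute", "match_dense", "match_gap", "joint")


def extract_chi(
    measured: BinodalPoint,
    model_n: float,
    mode: str = "match_dilute",
    bracket_scale: float = 2.0,
) -> float:
    """Interaction parameter chi reproducing a measured coexistence observable.

    Modes: ``match_dilute`` / ``match_dense`` match one branch,
    ``match_gap`` matches phi_beta - phi_alpha, ``joint`` minimizes the
    summed squared log-offsets of both branches. The search bracket is
    (chi_c, bracket_scale * chi_c].
    """
    if mode not in _CHI_MODES:
        raise ValueError(f"mode must be one of {_CHI_MODES}")
    _, chi_c = critical_point(model_n)
    lo, hi = chi_c * (1 + 1e-7), chi_c * bracket_scale

    def observable(chi: float) -> float:
        b = solve_binodal(FHModel(model_n, chi))
        if mode == "match_dilute":
            return np.log(b.phi_alpha) - np.log(measured.phi_alpha)
        if mode == "match_dense":
            return b.phi_beta - measured.phi_beta
        if mode == "match_gap":
            return (b.phi_beta - b.phi_alpha) - (measured.phi_beta - measured.phi_alpha)
        raise AssertionError

    if mode == "joint":
        from scipy.optimize import minimize_scalar

        def cost(chi: float) -> float:
            b = solve_binodal(FHModel(model_n, chi))
            return (np.log(b.phi_alpha / measured.phi_alpha) ** 2
                    + np.log(b.phi_beta / measured.phi_beta) ** 2)

        res = minimize_scalar(cost, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        return float(res.x)

    f_lo, f_hi = observable(lo), observable(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"observable not attainable for chi in ({lo:.4f}, {hi:.4f}] "
            f"(mode {mode}); endpoint mismatches {f_lo:.3g}, {f_hi:.3g}"
        )
    return brentq(observable, lo, hi, xtol=1e-12, rtol=_RTOL)
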