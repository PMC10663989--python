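"""Scheutjens-Fleer self-consistent lattice theory for a liquid-liquid interface.

A binary lattice of homopolymer (N segments) and one-site solvent with a
composition gradient along z only. The converged profile phi(z) satisfies
the self-consistency loop: segment weights G(z) = exp(-u(z)); chain
propagators built by the first-order Markov recursion with the three-layer
average (fraction ``lambda_bond`` in each adjacent layer) and mirrored
boundaries; composition from the two-sided propagator product, normalized
canonically to the fixed total polymer amount theta = mean_phi * L; and the
field u(z) carrying the Flory-Huggins exchange interaction plus the exact
incompressibility constraint (solvent eliminated, phi_s = 1 - phi_p).

The surface tension is the excess grand potential of the box over a
lever-rule split of the same material into the two coexisting bulk phases:
gamma b^2 / kT = F_box - L_alpha f(phi_alpha) - L_beta f(phi_beta), which
equals F - sum_i mu_i n_i minus the bulk grand potential because the
lever rule conserves both species. The canonical free energy of the box is
evaluated from the converged field and single-chain partition sum,

    F = n_p ln n_p - n_p - n_p ln Q_p - sum_z u(z) phi(z)
        + sum_z [phi_s ln phi_s - phi_s] + chi sum_z phi <1 - phi>,

whose homogeneous limit is the Flory-Huggins free energy up to terms linear
in the (conserved) amounts. The interfacial width is quantified by fitting
phi(z) = a - b * tanh(2 (z - z0) / w) with z in physical units via the
lattice size b.

Iteration uses Anderson mixing over the substitution map (plain damped
substitution develops limit cycles at deep quenches), with a damped-Picard
polish as fallback. Convergence is declared on the fixed-point residual
max|phi_new - phi| < tolerance; non-converged results are flagged, never
silently returned as converged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from dropsf._scf_kernels import density_from_field, lam_avg, picard, propagators_lam, scf_map
from dropsf.constants import BOLTZMANN
from dropsf.flory_huggins import FHModel, critical_point, solve_binodal

__all__ = [
    "SCFConfig", "SCFProfile", "SCFResult", "TanhFitParams",
    "solve_scf", "surface_tension_from_profile", "fit_interface_width",
    "end_segment_profile", "continuation_sweep", "width_maps",
    "profile_free_energy", "interpolate_gamma",
]


@dataclass(frozen=True)
class SCFConfig:
    """Run configuration for one lattice calculation.

    Defaults are the condensate-interface protocol: 200 layers, cubic
    lattice (lambda = 1/6), overall polymer volume fraction 0.06 (just
    below the critical ~0.061 for N around 235), lattice size 5.12 A,
    T = 295.15 K, cold starts confined to the first 30 layers.
    """

    chain_length: int
    chi: float
    n_layers: int = 200
    lambda_bond: float = 1.0 / 6.0
    mean_phi: float = 0.06
    lattice_size_A: float = 5.12
    tolerance: float = 1e-9
    max_iterations: int = 20000
    init_profile: np.ndarray | None = None
    init_restrict_layers: int = 30
    temperature: float = 295.15

    def __post_init__(self) -> None:
        if not 0 < self.lambda_bond <= 0.5:
            raise ValueError("lambda_bond must lie in (0, 1/2]")
        if not 0 < self.mean_phi < 1:
            raise ValueError("mean_phi must lie in (0, 1)")
        if self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")
        if self.n_layers < 3:
            raise ValueError("n_layers must be >= 3")

    @property
    def theta(self) -> float:
        """Total polymer amount per lattice column."""
        return self.mean_phi * self.n_layers

    @property
    def molecules_per_column(self) -> float:
        """Equivalent number of chains per column of the lattice."""
        return self.theta / self.chain_length

    @property
    def kT_over_b2(self) -> float:
        """kT / b^2 in N/m: the lattice unit of surface tension."""
        b = self.lattice_size_A * 1e-10
        return BOLTZMANN * self.temperature / b**2


@dataclass(frozen=True)
class SCFProfile:
    """Converged (or flagged) state of one SCF calculation."""

    phi_p: np.ndarray
    field: np.ndarray
    phi_end: np.ndarray
    converged: bool
    iterations: int
    residual: float

    @property
    def phi_solvent(self) -> np.ndarray:
        return 1.0 - self.phi_p


@dataclass(frozen=True)
class TanhFitParams:
    """phi(z) = offset - amplitude * tanh(2 (z - center) / width); width > 0."""

    offset: float
    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")


@dataclass(frozen=True)
class SCFResult:
    """Surface tension and width for one converged interface."""

    chi: float
    chain_length: int
    gamma_lattice: float          # gamma b^2 / kT
    gamma_si: float               # uN/m
    width_fit: TanhFitParams | None
    bulk_phi: tuple[float, float]
    converged: bool
    single_interface: bool = True
    profile: SCFProfile | None = field(default=None, repr=False, compare=False)


def _initial_profile(config: SCFConfig) -> np.ndarray:
    if config.init_profile is not None:
        phi = np.asarray(config.init_profile, dtype=float).copy()
        if phi.shape != (config.n_layers,):
            raise ValueError("init_profile length must equal n_layers")
        return phi * (config.theta / phi.sum())
    phi = np.full(config.n_layers, 1e-10)
    # widen the confinement region if it cannot hold theta below phi = 0.9
    k = min(max(config.init_restrict_layers, int(np.ceil(config.theta / 0.9))),
            config.n_layers)
    phi[:k] = config.theta / k
    return np.clip(phi * (config.theta / phi.sum()), 1e-12, 0.95)


def _anderson(phi, n, chi, lam, theta, tol, max_iter, beta=0.2, depth=6):
    """Anderson-accelerated fixed point of the substitution map."""
    xs: list[np.ndarray] = []
    gs: list[np.ndarray] = []
    u = np.zeros_like(phi)
    res = np.inf
    for it in range(max_iter):
        g, u = scf_map(phi, n, chi, lam, theta)
        f = g - phi
        res = float(np.abs(f).max())
        if res < tol:
            return phi, u, it + 1, res
        xs.append(phi.copy())
        gs.append(g.copy())
        if len(xs) > depth + 1:
            xs.pop(0)
            gs.pop(0)
        k = len(xs) - 1
        if k == 0:
            nxt = phi + beta * f
        else:
            F = np.array([gs[i] - xs[i] for i in range(k + 1)])
            dF = F[1:] - F[:-1]
            dX = np.array(xs[1:]) - np.array(xs[:-1])
            coef, *_ = np.linalg.lstsq(dF.T, f, rcond=1e-12)
            nxt = phi + beta * f - (dX + beta * dF).T @ coef
        bad = ~np.isfinite(nxt) | (nxt <= 0.0) | (nxt >= 1.0)
        if bad.any():
            nxt = np.where(bad, phi + 0.1 * f, nxt)
            nxt = np.clip(nxt, 1e-300, 1.0 - 1e-12)
            xs.clear()
            gs.clear()
        nxt *= theta / nxt.sum()
        phi = nxt
    return phi, u, max_iter, res


def _end_profile(u: np.ndarray, n: int, theta: float, lam: float) -> np.ndarray:
    """Volume-fraction profile of the chain-end segments (ranks 1 and N)."""
    Gs = propagators_lam(u - u.min(), n, lam)
    G = Gs[0]
    w = np.zeros_like(G)
    for s in range(n):
        w += Gs[s] * Gs[n - 1 - s] / G
    C = theta / w.sum()
    ends = Gs[0] * Gs[n - 1] / G
    if n == 1:
        return C * ends
    return 2.0 * C * ends


def rank_profiles(profile: SCFProfile, config: SCFConfig) -> np.ndarray:
    """phi(z, s) for every segment rank s; rows sum to phi_p(z)."""
    n, lam, theta = config.chain_length, config.lambda_bond, config.theta
    u = profile.field
    Gs = propagators_lam(u - u.min(), n, lam)
    G = Gs[0]
    w = Gs * Gs[::-1] / G
    C = theta / w.sum()
    return C * w


def solve_scf(config: SCFConfig) -> SCFProfile:
    """Iterate the lattice equations to self-consistency.

    Anderson mixing first; if the residual target is missed, a damped
    substitution polish runs from the best iterate. Canonical conservation
    (sum phi = theta) and incompressibility hold exactly at every step.
    """
    phi = _initial_profile(config)
    n, chi, lam, theta = (config.chain_length, config.chi,
                          config.lambda_bond, config.theta)
    phi, u, it1, res = _anderson(phi, n, chi, lam, theta,
                                 config.tolerance, config.max_iterations)
    it2 = 0
    if res >= config.tolerance:
        phi, u, it2, res = picard(phi, n, chi, lam, theta,
                                  config.tolerance, config.max_iterations, 0.02)
    converged = res < config.tolerance
    return SCFProfile(
        phi_p=phi,
        field=u,
        phi_end=_end_profile(u, n, theta, lam),
        converged=converged,
        iterations=it1 + it2,
        residual=res,
    )


# ---------------------------------------------------------------------------
# free energy and surface tension


def _free_energy_at_field(phi: np.ndarray, u: np.ndarray, n: int, chi: float,
                          lam: float) -> float:
    """Canonical free energy (kT per column) of a profile with its field.

    Valid whenever the canonical density generated by ``u`` equals ``phi``;
    additive constants linear in the conserved amounts are dropped
    consistently with ``_f_bulk``.
    """
    theta = float(phi.sum())
    n_p = theta / n
    _, Q = density_from_field(u, n, theta, lam)
    uu = u - u.min()
    # gauge invariant: shifting u by a constant changes -n_p ln Q and
    # -sum(u phi) by opposite amounts
    f_chain = n_p * np.log(n_p) - n_p - n_p * np.log(Q) - float((uu * phi).sum())
    phis = 1.0 - phi
    f_solvent = float((phis * np.log(phis)).sum() - phis.sum())
    avg = np.empty_like(phi)
    lam_avg(phis, lam, avg)
    energy = chi * float((phi * avg).sum())
    return f_chain + f_solvent + energy


def _f_bulk(phi: float, n: int, chi: float) -> float:
    """Homogeneous free energy per site, same constant conventions."""
    return ((phi / n) * (np.log(phi / n) - 1.0)
            + (1.0 - phi) * (np.log(1.0 - phi) - 1.0)
            + chi * phi * (1.0 - phi))


def profile_free_energy(phi, n: int, chi: float, lam: float = 1.0 / 6.0,
                        tol: float = 1e-12, max_iter: int = 100000):
    """Free energy (kT per column) of arbitrary admissible profiles.

    Chain conformational entropy is not a local functional of phi for
    N >= 2, so the defining field is recovered per profile by the fixed
    point u <- u + log(phi[u] / phi_target); the free energy is then
    evaluated at that field. Accepts a single profile (L,) or a batch
    (B, L); intended for small lattices (the per-profile cost grows with
    N and L). The converged SCF profile minimizes this functional at
    fixed total amount.
    """
    phi = np.asarray(phi, dtype=float)
    single = phi.ndim == 1
    P = phi[None, :] if single else phi
    if np.any((P <= 0) | (P >= 1)):
        raise ValueError("profiles must lie strictly inside (0, 1)")
    B, L = P.shape
    theta = P.sum(axis=1)

    u = -np.log(P)

    def batch_density(u):
        G = np.exp(-(u - u.min(axis=1, keepdims=True)))
        Gs = np.empty((n, B, L))
        Gs[0] = G
        for s in range(1, n):
            avg = np.empty_like(G)
            avg[:, 0] = (1 - lam) * Gs[s - 1][:, 0] + lam * Gs[s - 1][:, 1]
            avg[:, -1] = (1 - lam) * Gs[s - 1][:, -1] + lam * Gs[s - 1][:, -2]
            avg[:, 1:-1] = (lam * Gs[s - 1][:, :-2] + (1 - 2 * lam) * Gs[s - 1][:, 1:-1]
                            + lam * Gs[s - 1][:, 2:])
            Gs[s] = G * avg
        w = (Gs * Gs[::-1]).sum(axis=0) / G
        C = theta / w.sum(axis=1)
        return C[:, None] * w, Gs[n - 1].sum(axis=1)

    step = 1.0 if n == 1 else 0.5
    for _ in range(max_iter):
        dens, Q = batch_density(u)
        err = np.abs(dens - P).max()
        if err < tol:
            break
        upd = u + step * np.log(dens / P)
        # extreme profiles can overshoot; clamp the field excursion
        u = np.clip(upd, -200.0, 200.0)
        if not np.all(np.isfinite(u)):
            raise RuntimeError("field inversion produced non-finite fields")
    else:
        raise RuntimeError(f"field inversion did not reach {tol:g} (residual {err:g})")

    n_p = theta / n
    umin = u.min(axis=1, keepdims=True)
    f_chain = (n_p * np.log(n_p) - n_p - n_p * np.log(Q)
               - ((u - umin) * P).sum(axis=1))
    Ps = 1.0 - P
    f_solvent = (Ps * np.log(Ps)).sum(axis=1) - Ps.sum(axis=1)
    avg = np.empty_like(Ps)
    avg[:, 0] = (1 - lam) * Ps[:, 0] + lam * Ps[:, 1]
    avg[:, -1] = (1 - lam) * Ps[:, -1] + lam * Ps[:, -2]
    avg[:, 1:-1] = lam * Ps[:, :-2] + (1 - 2 * lam) * Ps[:, 1:-1] + lam * Ps[:, 2:]
    energy = chi * (P * avg).sum(axis=1)
    out = f_chain + f_solvent + energy
    return float(out[0]) if single else out


def _is_single_interface(phi: np.ndarray) -> bool:
    """Exactly one crossing of the mid-composition level.

    Counting midpoint crossings tolerates the damped layering oscillations
    that sharp lattice interfaces develop at deep quenches, while still
    catching a second interface in the box.
    """
    mid = 0.5 * (phi.max() + phi.min())
    above = phi > mid
    return int(np.count_nonzero(np.diff(above))) == 1


def surface_tension_from_profile(profile: SCFProfile, config: SCFConfig) -> SCFResult:
    """Excess grand potential of the box -> gamma (lattice and SI units).

    For chi below critical, or a flat profile, the reference is the uniform
    state and gamma is zero up to numerical noise.
    """
    n, chi, lam = config.chain_length, config.chi, config.lambda_bond
    phi, u = profile.phi_p, profile.field
    L = config.n_layers
    theta = config.theta
    F_box = _free_energy_at_field(phi, u, n, chi, lam)
    _, chi_c = critical_point(n)
    flat = phi.max() - phi.min() < 1e-6
    if chi <= chi_c or flat:
        gamma_lat = F_box - L * _f_bulk(theta / L, n, chi)
        bulk = (theta / L, theta / L)
    else:
        b = solve_binodal(FHModel(n, chi))
        L_beta = (theta - L * b.phi_alpha) / (b.phi_beta - b.phi_alpha)
        if not 0 <= L_beta <= L:
            raise ValueError(
                "overall composition falls outside the coexistence window; "
                "no interface in the box")
        F_ref = ((L - L_beta) * _f_bulk(b.phi_alpha, n, chi)
                 + L_beta * _f_bulk(b.phi_beta, n, chi))
        gamma_lat = F_box - F_ref
        bulk = (b.phi_alpha, b.phi_beta)
        # plateau equilibration check
        lo, hi = sorted((float(phi[:3].mean()), float(phi[-3:].mean())))
        if abs(lo - b.phi_alpha) > 1e-3 * max(b.phi_alpha, 1e-12) + 1e-6 or \
           abs(hi - b.phi_beta) > 1e-3:
            raise ValueError("bulk plateaus not equilibrated to coexistence")
    width = None
    if not flat:
        try:
            width = fit_interface_width(profile, config)
        except RuntimeError:
            width = None
    return SCFResult(
        chi=chi,
        chain_length=n,
        gamma_lattice=float(gamma_lat),
        gamma_si=float(gamma_lat) * config.kT_over_b2 * 1e6,
        width_fit=width,
        bulk_phi=bulk,
        converged=profile.converged,
        single_interface=_is_single_interface(phi),
    )


def fit_interface_width(profile: SCFProfile, config: SCFConfig) -> TanhFitParams:
    """Least-squares tanh fit of the composition profile; width in nm."""
    phi = profile.phi_p
    z = np.arange(1, config.n_layers + 1) * (config.lattice_size_A / 10.0)  # nm

    def f(z, a, b_amp, z0, w):
        return a - b_amp * np.tanh(2.0 * (z - z0) / w)

    half = 0.5 * (phi.max() + phi.min())
    z0_guess = z[int(np.argmin(np.abs(phi - half)))]
    amp_guess = 0.5 * (phi.max() - phi.min())
    sign = 1.0 if phi[0] > phi[-1] else -1.0
    p0 = [half, sign * amp_guess, z0_guess, 8.0 * config.lattice_size_A / 10.0]
    try:
        popt, _ = curve_fit(f, z, phi, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"tanh fit failed: {exc}") from exc
    a, b_amp, z0, w = popt
    if b_amp < 0:  # normalize orientation so width is positive
        b_amp, w = -b_amp, -w
    return TanhFitParams(offset=float(a), amplitude=float(b_amp),
                         center=float(z0), width=float(abs(w)))


def end_segment_profile(config: SCFConfig, profile: SCFProfile | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Rescaled all-segment and end-segment profiles (both mapped to [0, 1]).

    End segments are the chain's two terminal ranks. At an interface the
    rescaled end profile lies above the all-segment profile on the dilute
    side: chain ends pay less conformational free energy to stray into the
    polymer-poor phase than inner segments do.
    """
    if profile is None:
        profile = solve_scf(config)

    def rescale(x):
        return (x - x.min()) / (x.max() - x.min())

    return rescale(profile.phi_p), rescale(profile.phi_end)


# ---------------------------------------------------------------------------
# sweeps


def continuation_sweep(
    base: SCFConfig,
    chi_start: float = 0.741658,
    chi_step: float = 0.005,
    chi_extra: Sequence[float] = (),
    chi_stop: float | None = None,
    keep_profiles: bool = False,
) -> list[SCFResult]:
    """Warm-started descent in chi from a confined cold start.

    The first solve runs at ``chi_start`` with polymer confined to the
    first ``init_restrict_layers`` layers; each subsequent chi on the
    step grid (merged with ``chi_extra``) starts from the previous
    converged profile. The descent stops below the critical chi (or at
    ``chi_stop``). This protocol keeps exactly one interface in the box,
    which is verified per point via profile monotonicity.
    """
    _, chi_c = critical_point(base.chain_length)
    if chi_start <= chi_c:
        raise ValueError(f"chi_start must exceed chi_c = {chi_c:.6f}")
    floor = chi_c if chi_stop is None else max(chi_stop, chi_c)
    grid = []
    c = chi_start
    while c > floor:
        grid.append(round(c, 9))
        c -= chi_step
    grid = sorted({*grid, *[x for x in chi_extra if floor < x <= chi_start]},
                  reverse=True)
    results: list[SCFResult] = []
    phi_prev: np.ndarray | None = None
    for chi in grid:
        cfg = replace(base, chi=chi, init_profile=phi_prev)
        prof = solve_scf(cfg)
        res = surface_tension_from_profile(prof, cfg)
        if keep_profiles:
            res = replace(res, profile=prof)
        results.append(res)
        phi_prev = prof.phi_p
    return results


def interpolate_gamma(results: Sequence[SCFResult]) -> Callable[[float], float]:
    """Monotone cubic interpolant of gamma_si(chi) over converged sweep points."""
    from scipy.interpolate import PchipInterpolator

    pts = sorted((r.chi, r.gamma_si) for r in results if r.converged)
    chis = np.array([p[0] for p in pts])
    gams = np.array([p[1] for p in pts])
    return PchipInterpolator(chis, gams)


def width_maps(n_list: Sequence[int], chi_grid: Sequence[float],
               config: SCFConfig | None = None) -> pd.DataFrame:
    """Long-format (N, chi, gamma, width) table from per-N continuation sweeps."""
    rows = []
    for n in n_list:
        base = (replace(config, chain_length=n, init_profile=None)
                if config is not None else SCFConfig(chain_length=n, chi=max(chi_grid)))
        chi_start = max(max(chi_grid), 0.741658)
        results = continuation_sweep(base, chi_start=chi_start,
                                     chi_extra=list(chi_grid))
        wanted = {round(c, 9) for c in chi_grid}
        for r in results:
            if round(r.chi, 9) in wanted:
                rows.append({
                    "N": n,
                    "chi": r.chi,
                    "gamma_uN_m": r.gamma_si,
                    "width_nm": r.width_fit.width if r.width_fit else np.nan,
                    "converged": r.converged,
                })
    return pd.DataFrame(rows)
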