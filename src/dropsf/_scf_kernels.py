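"""Numba kernels for the lattice self-consistent-field iteration.

The lattice has L layers along z with mirrored boundaries; within-layer
structure is mean-field. ``lam`` is the fraction of neighbour sites in each
adjacent layer (1/6 for a cubic lattice). Chains are freely jointed
first-order Markov walks; the chain propagator obeys

    G(z, s|1) = G(z) <G(z, s-1|1)>

with G(z) = exp(-u(z)) and <.> the (lam, 1-2 lam, lam) layer average.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def lam_avg(a, lam, out):
    L = a.shape[0]
    out[0] = (1.0 - lam) * a[0] + lam * a[1]
    for z in range(1, L - 1):
        out[z] = lam * a[z - 1] + (1.0 - 2.0 * lam) * a[z] + lam * a[z + 1]
    out[L - 1] = (1.0 - lam) * a[L - 1] + lam * a[L - 2]


@njit(cache=True)
def propagators_lam(u, n, lam):
    """All forward propagators G(z, s|1), s = 1..n, from a gauge-shifted field."""
    L = u.shape[0]
    G = np.exp(-(u - u.min()))
    Gs = np.empty((n, L))
    Gs[0] = G
    tmp = np.empty(L)
    for s in range(1, n):
        lam_avg(Gs[s - 1], lam, tmp)
        for z in range(L):
            Gs[s, z] = G[z] * tmp[z]
    return Gs


@njit(cache=True)
def density_from_field(u, n, theta, lam):
    """Canonical polymer density and single-chain partition sum.

    phi(z) = C sum_s G(z,s|1) G(z,n-s+1|1) / G(z), with C fixed so that
    sum_z phi = theta.
    """
    L = u.shape[0]
    Gs = propagators_lam(u, n, lam)
    G = Gs[0]
    w = np.zeros(L)
    for s in range(n):
        for z in range(L):
            w[z] += Gs[s, z] * Gs[n - 1 - s, z] / G[z]
    Q = Gs[n - 1].sum()
    C = theta / w.sum()
    return C * w, Q


@njit(cache=True)
def scf_map(phi, n, chi, lam, theta):
    """One substitution step: profile -> exchange field -> new profile.

    Incompressibility is exact by construction (solvent = 1 - phi); the
    field is the polymer-solvent exchange potential plus the solvent
    elimination term, gauge constants being absorbed by the canonical
    normalization.
    """
    L = phi.shape[0]
    u = np.empty(L)
    avg = np.empty(L)
    lam_avg(phi, lam, avg)
    for z in range(L):
        u[z] = chi * (1.0 - 2.0 * avg[z]) - np.log1p(-phi[z])
    phi_new, Q = density_from_field(u, n, theta, lam)
    return phi_new, u


@njit(cache=True)
def picard(phi, n, chi, lam, theta, tol, max_iter, damping):
    """Damped substitution with stagnation-triggered damping reduction.

    Robust but slow; used as a fallback polish when Anderson mixing fails
    to reach the target residual.
    """
    res = 1.0
    d = damping
    best = 1e300
    last_improvement = 0
    u = np.empty(phi.shape[0])
    it = 0
    while it < max_iter:
        phi_new, u = scf_map(phi, n, chi, lam, theta)
        res = np.abs(phi_new - phi).max()
        if res < best:
            best = res
            last_improvement = it
            if d < damping:
                d = min(d * 1.02, damping)
        elif it - last_improvement > 100 and d > 1e-4:
            d *= 0.5
            last_improvement = it
        for z in range(phi.shape[0]):
            phi[z] += d * (phi_new[z] - phi[z])
        it += 1
        if res < tol:
            break
    return phi, u, it, res
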