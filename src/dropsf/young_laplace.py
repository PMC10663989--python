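"""Axisymmetric Young-Laplace (Bashforth-Adams) drop profiles.

A sessile drop of a phase denser than its surroundings, with rotational
symmetry about the vertical axis, has a meridian governed by

    dpsi/ds = 2/R0 + h/lc^2 - sin(psi)/r
    dr/ds   = cos(psi)
    dh/ds   = sin(psi)

with arc length ``s`` from the apex, tilt ``psi`` relative to the
horizontal, radius ``r`` and depth ``h`` measured downward from the apex.
``R0`` is the apex radius of curvature and ``lc`` the capillary length
sqrt(gamma / (delta_rho * g)). The + sign on h/lc^2 flattens the drop
toward a puddle as depth grows. At the apex the geometric term sin(psi)/r
tends to 1/R0, which regularizes the singularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


@dataclass(frozen=True)
class YLParameters:
    """Apex radius R0, capillary length lc, and integration bound s_max.

    All three share one length unit (the caller's choice)."""

    apex_radius: float
    capillary_length: float
    s_max: float

    def __post_init__(self) -> None:
        if self.apex_radius <= 0 or self.capillary_length <= 0 or self.s_max <= 0:
            raise ValueError("R0, lc and s_max must all be positive")


@dataclass(frozen=True)
class ProfileCurve:
    """One integrated meridian: arrays (s, psi, r, h) with origin at the apex."""

    arc_length: np.ndarray
    tilt: np.ndarray
    radius: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.arc_length)
        if not (len(self.tilt) == len(self.radius) == len(self.depth) == n):
            raise ValueError("profile arrays must share one length")

    def as_array(self) -> np.ndarray:
        """Columns (s, psi, r, h)."""
        return np.column_stack([self.arc_length, self.tilt, self.radius, self.depth])


@njit(cache=True)
def _rhs(psi, r, h, r0, inv_lc2):
    if r > 1e-12 * r0:
        geom = np.sin(psi) / r
    else:
        # apex limit: both principal curvatures equal, so sin(psi)/r -> dpsi/ds
        geom = 0.5 * (2.0 / r0 + h * inv_lc2)
    return 2.0 / r0 + h * inv_lc2 - geom, np.cos(psi), np.sin(psi)


@njit(cache=True)
def _rk4(r0, inv_lc2, s_max, n):
    ds = s_max / n
    out = np.empty((n + 1, 3))
    out[0, 0] = 0.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    # series start: near the apex the meridian is a circle of radius R0
    psi = ds / r0
    r = r0 * np.sin(ds / r0)
    h = r0 * (1.0 - np.cos(ds / r0))
    out[1, 0], out[1, 1], out[1, 2] = psi, r, h
    for i in range(1, n):
        a1, b1, c1 = _rhs(psi, r, h, r0, inv_lc2)
        a2, b2, c2 = _rhs(psi + 0.5 * ds * a1, r + 0.5 * ds * b1, h + 0.5 * ds * c1, r0, inv_lc2)
        a3, b3, c3 = _rhs(psi + 0.5 * ds * a2, r + 0.5 * ds * b2, h + 0.5 * ds * c2, r0, inv_lc2)
        a4, b4, c4 = _rhs(psi + ds * a3, r + ds * b3, h + ds * c3, r0, inv_lc2)
        psi += (ds / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
        r += (ds / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
        h += (ds / 6.0) * (c1 + 2 * c2 + 2 * c3 + c4)
        out[i + 1, 0], out[i + 1, 1], out[i + 1, 2] = psi, r, h
        if not (np.isfinite(psi) and np.isfinite(r) and np.isfinite(h)):
            return out[: i + 2], i + 1
    return out, -1


def integrate_profile(params: YLParameters, step: float | None = None,
                      stop_at_closure: bool = True) -> ProfileCurve:
    """Integrate the meridian from the apex to s = s_max.

    Fixed-step classic Runge-Kutta; default step is s_max/4000. The first
    step leaves the apex on the series expansion psi = s/R0 + O(s^3), which
    sidesteps the 0/0 in sin(psi)/r. By default the curve is truncated
    where the tilt reaches pi (the drop closes on itself; beyond that the
    solution is unphysical).
    """
    if step is None:
        step = params.s_max / 4000.0
    if step <= 0:
        raise ValueError("step must be positive")
    n = max(int(np.ceil(params.s_max / step)), 2)
    out, fail = _rk4(params.apex_radius, 1.0 / params.capillary_length**2, params.s_max, n)
    if fail >= 0:
        raise ArithmeticError(f"non-finite state at s = {fail * params.s_max / n:g}")
    s = np.linspace(0.0, params.s_max, n + 1)
    if stop_at_closure:
        closed = np.nonzero(out[:, 0] >= np.pi)[0]
        if closed.size:
            cut = closed[0] + 1
            s, out = s[:cut], out[:cut]
    return ProfileCurve(arc_length=s, tilt=out[:, 0], radius=out[:, 1], depth=out[:, 2])


def drop_volume(curve: ProfileCurve, height: float) -> float:
    """Volume of the solid of revolution down to the given depth.

    The arc length bound is recomputed as the first s with h(s) = height,
    then ``V = integral_0^smax pi r(s)^2 sin(psi(s)) ds`` with r(s) the
    cumulative integral of cos(psi). Monotone in height.
    """
    if height < 0:
        raise ValueError("height must be non-negative")
    if height == 0:
        return 0.0
    h = curve.depth
    if height > h[-1]:
        # allow small overshoot from pixel-quantized height measurements
        if height <= 1.02 * h[-1]:
            height = h[-1]
        else:
            raise ValueError(
                f"height {height:g} exceeds the integrated depth {h[-1]:g}; "
                "integrate with a larger s_max"
            )
    idx = int(np.argmax(h >= height))
    # interpolate the crossing, then integrate on the truncated grid
    s = curve.arc_length
    if idx == 0:
        s_cut = s[0]
    else:
        f = (height - h[idx - 1]) / (h[idx] - h[idx - 1])
        s_cut = s[idx - 1] + f * (s[idx] - s[idx - 1])
    keep = s <= s_cut
    s_grid = np.append(s[keep], s_cut)
    psi_grid = np.interp(s_grid, s, curve.tilt)
    r_grid = np.interp(s_grid, s, curve.radius)
    integrand = np.pi * r_grid**2 * np.sin(psi_grid)
    return float(np.trapezoid(integrand, s_grid))


def profile_to_csv(curve: ProfileCurve, path: str) -> None:
    np.savetxt(
        path,
        curve.as_array(),
        delimiter=",",
        header="s,psi,r,h",
        comments="",
    )
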