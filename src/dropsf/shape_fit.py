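"""Fit Young-Laplace parameters (R0, lc) to an extracted edge profile.

The objective follows the drop-shape-analysis convention: integrate the
meridian over s in [0, s_max] with s_max fixed at 1.8x the path length of
the ordered edge points, and minimize the summed point-to-curve distance
(nearest neighbour against a densely sampled generated curve). The
condensate volume is then computed from the best-fit profile, with the arc
length recomputed as the first s reproducing the measured drop height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from dropsf.imaging import EdgeProfile
from dropsf.young_laplace import ProfileCurve, YLParameters, drop_volume, integrate_profile


@dataclass(frozen=True)
class ShapeFitResult:
    """Best-fit Young-Laplace parameters for one drop (lengths in um)."""

    apex_radius: float
    capillary_length: float
    residual: float               # mean point-to-curve distance, um
    volume_um3: float
    s_max_fit: float
    s_max_volume: float
    converged: bool = True
    gravity_insensitive: bool = False
    no_measurable_deformation: bool = False

    @property
    def volume_uL(self) -> float:
        return self.volume_um3 * 1e-9

    @property
    def volume_nL(self) -> float:
        return self.volume_um3 * 1e-6


def _path_length(points: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def _objective_factory(points: np.ndarray, s_max: float, n_points: int, squared: bool):
    def cost(logp: np.ndarray) -> float:
        r0, lc = np.exp(logp)
        try:
            curve = integrate_profile(
                YLParameters(r0, lc, s_max), step=s_max / n_points)
        except (ArithmeticError, ValueError):
            return 1e12
        tree = cKDTree(np.column_stack([curve.radius, curve.depth]))
        d, _ = tree.query(points, k=1)
        return float(np.sum(d**2) if squared else np.sum(d))

    return cost


def fit_profile(
    edge: EdgeProfile,
    init: YLParameters | None = None,
    objective: str = "distance",
    n_points: int = 4000,
    max_edge_points: int = 600,
    lc_unidentifiable_factor: float = 20.0,
) -> ShapeFitResult:
    """Nelder-Mead fit of (R0, lc) in log space, with multi-start.

    Starts from a spherical-cap estimate of R0 (osculating circle through
    near-apex points) and capillary lengths of 0.5x, 1x and 2x the drop
    height, unless an explicit ``init`` is supplied. ``objective`` is
    "distance" (sum of distances) or "squared" (sum of squares).

    Flags: ``gravity_insensitive`` when the drop height is below 0.3 lc
    (weak deformation, lc poorly constrained); ``no_measurable_deformation``
    when the fitted lc runs past ``lc_unidentifiable_factor`` drop heights
    (spherical cap; gamma unidentifiable).
    """
    if objective not in ("distance", "squared"):
        raise ValueError("objective must be 'distance' or 'squared'")
    points = edge.points
    if len(points) < 50:
        raise ValueError("need at least 50 edge points")
    height = edge.drop_height
    if points[:, 1].max() - points[:, 1].min() < 0.5 * height:
        raise ValueError("edge points must span at least half the drop height")
    spread = np.linalg.matrix_rank(points - points.mean(axis=0), tol=1e-6 * height)
    if spread < 2:
        raise ValueError("degenerate (collinear) edge")

    s_max = 1.8 * _path_length(points)
    fit_pts = points
    if len(points) > max_edge_points:
        idx = np.linspace(0, len(points) - 1, max_edge_points).astype(int)
        fit_pts = points[idx]
    cost = _objective_factory(fit_pts, s_max, n_points, objective == "squared")

    # spherical-cap R0 estimate from a point ~20% down the profile
    near = points[points[:, 1] <= 0.25 * height]
    if len(near) >= 2:
        r_est, h_est = near[-1]
        r0_est = (r_est**2 + h_est**2) / (2.0 * h_est) if h_est > 0 else height
    else:
        r0_est = height
    r0_est = max(r0_est, 1e-3 * height)

    if init is not None:
        starts = [(init.apex_radius, init.capillary_length)]
    else:
        starts = [(r0_est, f * height) for f in (0.5, 1.0, 2.0)]

    best = None
    for r0_0, lc_0 in starts:
        res = minimize(
            cost,
            np.log([r0_0, lc_0]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 600},
        )
        if best is None or res.fun < best.fun:
            best = res
    r0, lc = np.exp(best.x)

    # volume: extend the meridian until the measured height is reached
    s_vol = s_max
    curve = integrate_profile(YLParameters(r0, lc, s_vol))
    for _ in range(8):
        if curve.depth.max() >= height or curve.tilt[-1] >= np.pi * 0.999:
            break
        s_vol *= 1.6
        curve = integrate_profile(YLParameters(r0, lc, s_vol))
    volume = drop_volume(curve, height)
    i_cut = int(np.argmax(curve.depth >= height))
    s_max_volume = float(curve.arc_length[i_cut])

    n_used = len(fit_pts)
    residual = best.fun / n_used if objective == "distance" else np.sqrt(best.fun / n_used)
    return ShapeFitResult(
        apex_radius=float(r0),
        capillary_length=float(lc),
        residual=float(residual),
        volume_um3=float(volume),
        s_max_fit=float(s_max),
        s_max_volume=s_max_volume,
        converged=bool(best.success),
        gravity_insensitive=bool(height < 0.3 * lc),
        no_measurable_deformation=bool(lc > lc_unidentifiable_factor * height),
    )


def batch_capillary_lengths(results: list[ShapeFitResult]) -> tuple[float, float]:
    """Mean and sample standard deviation of lc over replicate drops."""
    if len(results) < 2:
        raise ValueError("need at least 2 fits")
    lcs = np.array([r.capillary_length for r in results])
    return float(lcs.mean()), float(lcs.std(ddof=1))


def generated_curve(result: ShapeFitResult, n_points: int = 4000) -> ProfileCurve:
    """The best-fit meridian, for plotting or export."""
    return integrate_profile(
        YLParameters(result.apex_radius, result.capillary_length, result.s_max_fit),
        step=result.s_max_fit / n_points,
    )
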