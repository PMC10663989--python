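"""Interface extraction from bright-field drop images, and synthetic renders.

The fluid-fluid interface of a sessile condensate appears as a strong
intensity edge between the dark drop and the light background. Edges are
found with Canny hysteresis detection; left and right branches are folded
about the fitted symmetry axis into a single (r, h) profile with origin at
the apex, and a running-mean filter of radius 5 is applied to the radii.

``render_synthetic_drop`` inverts the process: a Young-Laplace meridian is
revolved and rasterized (dark drop, light background), blurred and
corrupted with seeded Gaussian noise, providing ground-truth fixtures for
the extraction and fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage import feature, filters, measure

from dropsf.young_laplace import YLParameters, integrate_profile


class NoEdgeError(ValueError):
    """No drop silhouette found in the image."""


class MultipleDropsError(ValueError):
    """More than one sessile drop detected; sample needs re-coalescence."""


class AsymmetricDropError(ValueError):
    """Left/right branches differ beyond the asymmetry threshold (tilted drop)."""


@dataclass(frozen=True)
class DropImage:
    """Grayscale image with pixel-size calibration (um per pixel).

    Gravity must run along the row axis (apex at low rows)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 100:
            raise ValueError("need a 2-D grayscale image of at least 100x100 pixels")


@dataclass(frozen=True)
class EdgeProfile:
    """Folded interface coordinates in physical units, origin at the apex."""

    points: np.ndarray          # (n, 2) columns (r_um, h_um), ordered by h
    apex_pixel: tuple[float, float]
    drop_height: float          # um
    asymmetry: float            # mean |r_left - r_right| / mean r

    def __post_init__(self) -> None:
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")


def render_synthetic_drop(
    params: YLParameters,
    pixel_size: float,
    noise_sd: float = 0.0,
    blur_radius: float = 0.0,
    seed: int = 0,
    height: float | None = None,
    margin_px: int = 12,
) -> tuple[DropImage, dict]:
    """Rasterize a drop bounded by the integrated meridian; return ground truth.

    Lengths in um. ``height`` (apex-to-base) defaults to the depth where
    the meridian steepens past vertical incidence, i.e. a drop resting with
    a near-180-degree contact angle. Intensities: background 0.85, drop
    0.15, sub-pixel edge coverage, then Gaussian blur and seeded noise.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    curve = integrate_profile(params)
    psi, r, h = curve.tilt, curve.radius, curve.depth
    if height is None:
        past = np.nonzero(psi >= 0.98 * np.pi)[0]
        stop = past[0] if past.size else len(h) - 1
        height = float(h[stop])
    keep = h <= height
    if not np.any(psi[keep] >= 0.5 * np.pi) and h.max() < height:
        raise ValueError("meridian too short for requested height; raise s_max")
    h_prof, r_prof = h[keep], r[keep]

    r_max = float(r_prof.max())
    n_rows = int(np.ceil(height / pixel_size)) + 2 * margin_px
    n_cols = int(np.ceil(2 * r_max / pixel_size)) + 2 * margin_px
    if max(n_rows, n_cols) > 4096:
        raise ValueError("drop larger than canvas limit; increase pixel_size")
    n_rows, n_cols = max(n_rows, 100), max(n_cols, 100)

    apex_row = float(margin_px)
    cx = n_cols / 2.0
    rows = np.arange(n_rows)
    depth_um = (rows - apex_row) * pixel_size
    radius_px = np.interp(depth_um, h_prof, r_prof, left=np.nan, right=np.nan) / pixel_size
    radius_px = np.where(np.isnan(radius_px), -np.inf, radius_px)

    cols = np.arange(n_cols)
    dist = np.abs(cols[None, :] - cx)
    coverage = np.clip(radius_px[:, None] - dist + 0.5, 0.0, 1.0)
    img = 0.85 - 0.70 * coverage

    if blur_radius > 0:
        img = filters.gaussian(img, sigma=blur_radius, preserve_range=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    truth = {
        "R0_um": params.apex_radius,
        "lc_um": params.capillary_length,
        "pixel_size_um": pixel_size,
        "apex_row": apex_row,
        "apex_col": cx,
        "height_um": height,
        "pixel_volume_um3": float(np.pi * np.sum(
            np.clip(np.interp(depth_um, h_prof, r_prof, left=0.0, right=0.0), 0, None) ** 2
        ) * pixel_size),
    }
    return DropImage(pixels=img, pixel_size=pixel_size), truth


def _main_silhouette(pixels: np.ndarray) -> np.ndarray:
    """Boolean mask of the single drop; raises for zero or multiple drops."""
    thr = filters.threshold_otsu(pixels)
    dark = pixels < thr
    labels = measure.label(dark)
    regions = [reg for reg in measure.regionprops(labels) if reg.area >= 200]
    if not regions:
        raise NoEdgeError("no drop silhouette found")
    if len(regions) > 1:
        raise MultipleDropsError(
            f"{len(regions)} separate silhouettes found; re-coalesce the sample")
    return labels == regions[0].label


def extract_edge(
    image: DropImage,
    detector_sensitivity: float = 0.5,
    asymmetry_threshold: float = 0.02,
    smooth_radius: int = 5,
) -> EdgeProfile:
    """Detect the drop contour and fold it into a single (r, h) profile.

    Canny edge detection (sensitivity in (0, 1] maps to the hysteresis
    thresholds on the normalized image), restricted to the outline of the
    single dark silhouette. The symmetry axis minimizes the mean left/right
    radius mismatch; drops with residual asymmetry above the threshold are
    rejected as tilted.
    """
    if not 0 < detector_sensitivity <= 1:
        raise ValueError("detector_sensitivity must lie in (0, 1]")
    px = image.pixels.astype(float)
    lo, hi = float(px.min()), float(px.max())
    if hi - lo < 1e-12:
        raise NoEdgeError("blank image")
    px = (px - lo) / (hi - lo)  # affine intensity invariance

    mask = _main_silhouette(px)
    high = 0.45 - 0.40 * detector_sensitivity
    edges = feature.canny(px, sigma=2.0, low_threshold=high / 2.0, high_threshold=high)
    # keep edges belonging to the silhouette outline
    from scipy.ndimage import binary_dilation

    edges &= binary_dilation(mask, iterations=3)
    if not edges.any():
        raise NoEdgeError("no closed edge found")

    rows, cols = np.nonzero(edges)
    apex_row = rows.min()
    left, right = {}, {}
    for row in np.unique(rows):
        cc = cols[rows == row]
        left[row], right[row] = cc.min(), cc.max()
    usable = np.array([row for row in sorted(left) if right[row] - left[row] >= 2])
    if usable.size < 5:
        raise NoEdgeError("edge too short to form a profile")

    lcol = np.array([left[r] for r in usable], dtype=float)
    rcol = np.array([right[r] for r in usable], dtype=float)

    from scipy.optimize import minimize_scalar

    def mismatch(ax):
        return np.mean(np.abs((ax - lcol) - (rcol - ax)))

    ax0 = float(np.mean((lcol + rcol) / 2.0))
    res = minimize_scalar(mismatch, bounds=(ax0 - 20, ax0 + 20), method="bounded")
    axis = float(res.x)

    r_left = axis - lcol
    r_right = rcol - axis
    mean_r = float(np.mean((r_left + r_right) / 2.0))
    asymmetry = float(np.mean(np.abs(r_left - r_right)) / mean_r)
    if asymmetry > asymmetry_threshold:
        raise AsymmetricDropError(
            f"asymmetry {asymmetry:.3%} exceeds {asymmetry_threshold:.1%}; "
            "drop appears tilted")

    if smooth_radius > 0:
        size = 2 * smooth_radius + 1
        r_left = uniform_filter1d(r_left, size=size, mode="nearest")
        r_right = uniform_filter1d(r_right, size=size, mode="nearest")

    h_um = (usable - float(apex_row)) * image.pixel_size
    pts = np.empty((2 * usable.size, 2))
    pts[0::2, 0] = r_left * image.pixel_size
    pts[1::2, 0] = r_right * image.pixel_size
    pts[0::2, 1] = h_um
    pts[1::2, 1] = h_um
    return EdgeProfile(
        points=pts,
        apex_pixel=(float(apex_row), axis),
        drop_height=float(h_um[-1]),
        asymmetry=asymmetry,
    )


def load_image(path, pixel_size: float) -> DropImage:
    """Read an 8/16-bit grayscale TIFF or PNG."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return DropImage(pixels=arr.astype(float), pixel_size=pixel_size)


def save_image(image: DropImage, path) -> None:
    """Write as 8-bit PNG/TIFF."""
    import imageio.v3 as iio

    arr = np.clip(image.pixels, 0.0, 1.0)
    iio.imwrite(path, (arr * 255).astype(np.uint8))


def edge_to_csv(edge: EdgeProfile, path) -> None:
    np.savetxt(path, edge.points, delimiter=",", header="r_um,h_um", comments="")
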