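"""From (sample density, condensate volume fraction) batches to surface tension.

Mass and volume conservation in a two-phase sample of total volume nu_0 and
density rho_0, containing condensate volume nu_beta, gives

    nu_beta / nu_0 = (rho_0 - rho_alpha) / (rho_beta - rho_alpha)

so nu_beta/nu_0 is linear in rho_0 with gradient 1/delta_rho and x-intercept
rho_alpha. Ordinary least squares over a concentration series yields
delta_rho and rho_alpha with regression uncertainties; combined with the
capillary length lc this gives the surface tension gamma = delta_rho g lc^2.

Densities, volume fractions and molar concentrations interconvert through
ideal mixing: rho = (1 - phi) rho_s + phi m_p / v_p and phi = c v_p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from dropsf.constants import STANDARD_GRAVITY
from dropsf.sequence_props import ProteinSpec


@dataclass(frozen=True)
class SampleRecord:
    """One phase-separated sample.

    Units: rho_0 kg/m^3; volumes uL; capillary length um (optional)."""

    sample_density: float
    sample_volume: float
    condensate_volume: float
    capillary_length: float | None = None

    def __post_init__(self) -> None:
        if min(self.sample_density, self.sample_volume, self.condensate_volume) <= 0:
            raise ValueError("density and volumes must be positive")
        if self.condensate_volume >= self.sample_volume:
            raise ValueError("condensate volume must be below sample volume")

    @property
    def volume_ratio(self) -> float:
        return self.condensate_volume / self.sample_volume


@dataclass(frozen=True)
class DensityFitResult:
    """delta_rho and rho_alpha (kg/m^3) with regression standard deviations."""

    delta_rho: float
    delta_rho_sd: float
    rho_alpha: float
    rho_alpha_sd: float
    r_squared: float


@dataclass(frozen=True)
class TensionResult:
    """gamma (uN/m) with first-order propagated uncertainty."""

    gamma: float
    gamma_sd: float
    delta_rho: float
    delta_rho_sd: float
    capillary_length_um: float
    capillary_length_sd_um: float
    g: float = STANDARD_GRAVITY


def fit_density_line(records: Sequence[SampleRecord]) -> DensityFitResult:
    """OLS of y = nu_beta/nu_0 on x = rho_0; delta_rho = 1/slope, rho_alpha = x(y=0).

    Standard deviations come from the regression parameter covariance via
    first-order propagation (rho_alpha = -intercept/slope uses the full
    2x2 covariance).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records")
    x = np.array([r.sample_density for r in records])
    y = np.array([r.volume_ratio for r in records])
    if np.ptp(x) == 0:
        raise ValueError("records must span a range of rho_0")
    (m, c), cov = np.polyfit(x, y, 1, cov=True)
    if m <= 0:
        raise ValueError("non-positive slope: condensate not denser than the dilute phase")
    var_m, var_c = cov[0, 0], cov[1, 1]
    cov_mc = cov[0, 1]
    delta_rho = 1.0 / m
    delta_rho_sd = np.sqrt(var_m) / m**2
    rho_alpha = -c / m
    # gradient of (-c/m) wrt (m, c): (c/m^2, -1/m)
    grad = np.array([c / m**2, -1.0 / m])
    rho_alpha_sd = float(np.sqrt(grad @ cov @ grad))
    resid = y - (m * x + c)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return DensityFitResult(
        delta_rho=float(delta_rho),
        delta_rho_sd=float(delta_rho_sd),
        rho_alpha=float(rho_alpha),
        rho_alpha_sd=rho_alpha_sd,
        r_squared=r2,
    )


def surface_tension(
    delta_rho: float,
    lcap_um: float,
    delta_rho_sd: float = 0.0,
    lcap_sd_um: float = 0.0,
    g: float = STANDARD_GRAVITY,
) -> TensionResult:
    """gamma = delta_rho g lc^2, in uN/m (delta_rho kg/m^3, lc um).

    Relative uncertainty adds the delta_rho term and twice the lc term in
    quadrature.
    """
    if delta_rho <= 0 or lcap_um <= 0:
        raise ValueError("delta_rho and lc must be positive")
    lc = lcap_um * 1e-6
    gamma = delta_rho * g * lc**2 * 1e6  # N/m -> uN/m
    rel = np.sqrt((delta_rho_sd / delta_rho) ** 2 + (2.0 * lcap_sd_um / lcap_um) ** 2)
    return TensionResult(
        gamma=float(gamma),
        gamma_sd=float(gamma * rel),
        delta_rho=delta_rho,
        delta_rho_sd=delta_rho_sd,
        capillary_length_um=lcap_um,
        capillary_length_sd_um=lcap_sd_um,
        g=g,
    )


def density_from_volume_fraction(phi: float, spec: ProteinSpec,
                                 rho_solvent: float = 998.2) -> float:
    """Ideal-mixing density in kg/m^3: (1-phi) rho_s + phi m_p/v_p."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    protein_density = spec.molar_mass / spec.molar_volume * 1000.0  # g/cm^3 -> kg/m^3
    return (1.0 - phi) * rho_solvent + phi * protein_density


def volume_fraction_from_concentration(c_molar: float, spec: ProteinSpec) -> float:
    """phi = c v_p (c in mol/L, v_p in cm^3/mol)."""
    if c_molar < 0:
        raise ValueError("concentration must be non-negative")
    phi = c_molar * spec.molar_volume / 1000.0  # L/mol
    if phi > 1.0:
        raise ValueError(f"unphysical volume fraction {phi:.3g} > 1")
    return phi


def concentration_from_volume_fraction(phi: float, spec: ProteinSpec) -> float:
    """Inverse of volume_fraction_from_concentration, mol/L."""
    return phi * 1000.0 / spec.molar_volume


def dense_phase_concentration(
    fit: DensityFitResult,
    spec: ProteinSpec,
    c_alpha_molar: float,
    rho_solvent: float = 998.2,
) -> float:
    """Protein concentration inside the condensate, mol/L.

    Inverts the ideal-mixing density: the volume-fraction gap is
    delta_phi = delta_rho / (m_p/v_p - rho_s), and c_beta = c_alpha +
    delta_phi / v_p.
    """
    protein_density = spec.molar_mass / spec.molar_volume * 1000.0
    contrast = protein_density - rho_solvent
    if contrast <= 0:
        raise ValueError("protein mass density must exceed the solvent density")
    delta_phi = fit.delta_rho / contrast
    return c_alpha_molar + concentration_from_volume_fraction(delta_phi, spec)


def synthesize_density_batch(
    delta_rho: float,
    rho_alpha: float,
    n: int = 13,
    noise_sd: float = 5e-4,
    seed: int = 0,
    rho0_range: tuple[float, float] = (1001.0, 1031.0),
    sample_volume_uL: float = 80.0,
) -> list[SampleRecord]:
    """Synthetic concentration series obeying the conservation line.

    rho_0 is drawn uniformly over ``rho0_range`` (which must sit above
    rho_alpha), the volume ratio follows the exact linear law, and i.i.d.
    Gaussian noise of absolute scale ``noise_sd`` is added to the ratio.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if rho0_range[0] <= rho_alpha:
        raise ValueError("rho_0 range must lie above rho_alpha")
    rng = np.random.default_rng(seed)
    rho0 = np.sort(rng.uniform(*rho0_range, size=n))
    ratio = (rho0 - rho_alpha) / delta_rho + rng.normal(0.0, noise_sd, size=n)
    ratio = np.clip(ratio, 1e-9, None)
    return [
        SampleRecord(
            sample_density=float(r0),
            sample_volume=sample_volume_uL,
            condensate_volume=float(rat * sample_volume_uL),
        )
        for r0, rat in zip(rho0, ratio)
    ]


def records_from_csv(path) -> list[SampleRecord]:
    """Read records from CSV with columns rho0_kg_m3, v0_uL, vbeta_uL[, lcap_um]."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(SampleRecord(
            sample_density=row["rho0_kg_m3"],
            sample_volume=row["v0_uL"],
            condensate_volume=row["vbeta_uL"],
            capillary_length=row.get("lcap_um"),
        ))
    return out


def records_to_csv(records: Sequence[SampleRecord], path) -> None:
    pd.DataFrame(
        {
            "rho0_kg_m3": [r.sample_density for r in records],
            "v0_uL": [r.sample_volume for r in records],
            "vbeta_uL": [r.condensate_volume for r in records],
            "lcap_um": [r.capillary_length for r in records],
        }
    ).to_csv(path, index=False)
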