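"""End-to-end orchestration: images -> (R0, lc, volumes) -> (delta_rho,
rho_alpha) -> gamma -> chi -> lattice-theory comparison.

A run is driven by a RunConfig (loadable from YAML). With a synthetic spec
the pipeline renders drops and density batches from known ground truth and
reports recovered-vs-true deltas alongside the regular outputs, which is
how the whole workflow is validated without laboratory data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from dropsf import __version__
from dropsf.constants import STANDARD_GRAVITY
from dropsf.densitometry import (
    dense_phase_concentration,
    fit_density_line,
    records_from_csv,
    records_to_csv,
    surface_tension,
    synthesize_density_batch,
)
from dropsf.flory_huggins import BinodalPoint, extract_chi
from dropsf.imaging import extract_edge, load_image, render_synthetic_drop, save_image
from dropsf.scf import SCFConfig, continuation_sweep
from dropsf.sequence_props import bundled_proteins
from dropsf.shape_fit import batch_capillary_lengths, fit_profile
from dropsf.young_laplace import YLParameters


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth for a synthetic run (lengths um, densities kg/m^3)."""

    n_drops: int = 13
    apex_radius: float = 150.0
    capillary_length: float = 293.0
    pixel_size: float = 1.3
    noise_sd: float = 0.01
    blur_radius: float = 1.0
    delta_rho: float = 97.0
    rho_alpha: float = 1000.2
    n_density_samples: int = 13
    density_noise_sd: float = 5e-4
    radius_jitter: float = 0.10   # relative spread of R0 across drops


@dataclass(frozen=True)
class RunConfig:
    protein: str = "ddx4n_1-229"
    image_paths: tuple[str, ...] = ()
    density_csv: str | None = None
    synthetic: SyntheticSpec | None = None
    pixel_size: float = 1.3
    solvent_density: float = 998.2
    g: float = STANDARD_GRAVITY
    temperature: float = 295.15
    c_alpha_molar: float = 32e-6
    chi_mode: str = "match_dilute"
    scf_layers: int = 200
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.synthetic is None and not self.image_paths:
            raise ValueError("config needs image_paths or a synthetic spec")
        if self.synthetic is None and self.density_csv is None:
            raise ValueError("config needs a density_csv for measured runs")


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    payload = asdict(config)
    payload.pop("output_dir", None)  # where results land does not change them
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a JSON-ready report dict."""
    config.validate()
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    proteins = bundled_proteins()
    if config.protein not in proteins:
        raise StageError("config", ValueError(f"unknown protein {config.protein!r}"))
    spec = proteins[config.protein]
    report: dict = {
        "provenance": {
            "dropsf_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "protein": config.protein,
        }
    }

    # --- stage 1: drops ---
    try:
        rng = np.random.default_rng(config.seed)
        fits = []
        truths = []
        if config.synthetic is not None:
            syn = config.synthetic
            for i in range(syn.n_drops):
                r0 = syn.apex_radius * (1 + syn.radius_jitter * rng.uniform(-1, 1))
                params = YLParameters(r0, syn.capillary_length, s_max=6.0 * r0)
                img, truth = render_synthetic_drop(
                    params, syn.pixel_size, noise_sd=syn.noise_sd,
                    blur_radius=syn.blur_radius, seed=int(rng.integers(2**31)))
                truths.append(truth)
                edge = extract_edge(img)
                fits.append(fit_profile(edge))
                if outdir:
                    save_image(img, outdir / f"drop_{i:02d}.png")
        else:
            for path in config.image_paths:
                edge = extract_edge(load_image(path, config.pixel_size))
                fits.append(fit_profile(edge))
        lc_mean, lc_sd = batch_capillary_lengths(fits)
        report["drops"] = {
            "n": len(fits),
            "lc_um_mean": lc_mean,
            "lc_um_sd": lc_sd,
            "fits": [
                {"R0_um": f.apex_radius, "lc_um": f.capillary_length,
                 "residual_um": f.residual, "volume_nL": f.volume_nL}
                for f in fits
            ],
        }
        if truths:
            report["drops"]["truth_lc_um"] = config.synthetic.capillary_length
    except Exception as err:  # noqa: BLE001 - stage-tagged fail-fast
        raise StageError("drops", err) from err

    # --- stage 2: densitometry ---
    try:
        if config.synthetic is not None:
            syn = config.synthetic
            records = synthesize_density_batch(
                syn.delta_rho, syn.rho_alpha, n=syn.n_density_samples,
                noise_sd=syn.density_noise_sd, seed=config.seed + 1,
                rho0_range=(syn.rho_alpha + 0.1 * syn.delta_rho,
                            syn.rho_alpha + 0.4 * syn.delta_rho))
        else:
            records = records_from_csv(config.density_csv)
        if outdir:
            records_to_csv(records, outdir / "density_records.csv")
        dfit = fit_density_line(records)
        report["density"] = {
            "delta_rho_kg_m3": dfit.delta_rho,
            "delta_rho_sd": dfit.delta_rho_sd,
            "rho_alpha_kg_m3": dfit.rho_alpha,
            "rho_alpha_sd": dfit.rho_alpha_sd,
            "r_squared": dfit.r_squared,
        }
    except Exception as err:
        raise StageError("density", err) from err

    # --- stage 3: surface tension ---
    try:
        tension = surface_tension(dfit.delta_rho, lc_mean,
                                  dfit.delta_rho_sd, lc_sd, g=config.g)
        report["tension"] = {"gamma_uN_m": tension.gamma,
                             "gamma_sd_uN_m": tension.gamma_sd}
        if config.synthetic is not None:
            syn = config.synthetic
            gamma_true = syn.delta_rho * config.g * (syn.capillary_length * 1e-6) ** 2 * 1e6
            report["tension"]["truth_gamma_uN_m"] = gamma_true
            report["tension"]["relative_error"] = tension.gamma / gamma_true - 1.0
    except Exception as err:
        raise StageError("tension", err) from err

    # --- stage 4: interaction parameter ---
    try:
        c_beta = dense_phase_concentration(dfit, spec, config.c_alpha_molar,
                                           rho_solvent=config.solvent_density)
        phi_alpha = config.c_alpha_molar * spec.molar_volume / 1000.0
        phi_beta = c_beta * spec.molar_volume / 1000.0
        chi = extract_chi(BinodalPoint(phi_alpha, phi_beta),
                          spec.n_residues, mode=config.chi_mode)
        report["flory_huggins"] = {
            "phi_alpha_measured": phi_alpha,
            "phi_beta_measured": phi_beta,
            "c_beta_mM": c_beta * 1000.0,
            "chi": chi,
            "chi_mode": config.chi_mode,
        }
    except Exception as err:
        raise StageError("chi", err) from err

    # --- stage 5: lattice theory comparison ---
    try:
        base = SCFConfig(chain_length=spec.n_residues, chi=chi,
                         n_layers=config.scf_layers,
                         temperature=config.temperature)
        results = continuation_sweep(base, chi_extra=[chi], chi_stop=chi - 1e-12)
        at_chi = min(results, key=lambda r: abs(r.chi - chi))
        report["scf"] = {
            "chi": at_chi.chi,
            "gamma_uN_m": at_chi.gamma_si,
            "width_nm": at_chi.width_fit.width if at_chi.width_fit else None,
            "gamma_ratio_theory_over_measured": at_chi.gamma_si / tension.gamma,
            "converged": at_chi.converged,
        }
    except Exception as err:
        raise StageError("scf", err) from err

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    syn = raw.pop("synthetic", None)
    return RunConfig(
        synthetic=SyntheticSpec(**syn) if syn else None,
        image_paths=tuple(raw.pop("image_paths", ())),
        **raw,
    )


def make_fixtures(seed: int, outdir) -> dict:
    """Write the synthetic fixture tree (images, CSV, FASTA, truth JSON).

    Deterministic for fixed seed; returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "files": []}

    for i, (r0, lc) in enumerate([(150.0, 293.0), (120.0, 237.0), (170.0, 293.0)]):
        params = YLParameters(r0, lc, s_max=6.0 * r0)
        img, truth = render_synthetic_drop(params, pixel_size=1.3, noise_sd=0.01,
                                           blur_radius=1.0, seed=int(rng.integers(2**31)))
        name = f"drop_{i:02d}.png"
        save_image(img, outdir / name)
        with open(outdir / f"drop_{i:02d}.json", "w") as fh:
            json.dump(truth, fh, indent=2)
        manifest["files"] += [name, f"drop_{i:02d}.json"]

    records = synthesize_density_batch(97.0, 1000.2, n=13, noise_sd=5e-4,
                                       seed=seed, rho0_range=(1003.0, 1035.0))
    records_to_csv(records, outdir / "density_records.csv")
    manifest["files"].append("density_records.csv")

    import shutil
    from dropsf.sequence_props import _data_path

    shutil.copy(_data_path("ddx4n_synthetic.fasta"), outdir / "ddx4n_synthetic.fasta")
    manifest["files"].append("ddx4n_synthetic.fasta")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["files"].append("manifest.json")
    return manifest
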