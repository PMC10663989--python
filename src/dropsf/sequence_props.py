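"""Per-protein physical constants derived from sequence and tabulated values.

Net charge follows the Henderson-Hasselbalch equation with a fixed pKa table;
chain length, molar mass, molar volume and the 280 nm extinction coefficient
are tabulated inputs (they are measured/tabulated quantities, not predicted
here). The lattice size for mean-field calculations is the cube root of the
mean molecular volume per amino acid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml
from Bio import SeqIO

from dropsf.constants import AVOGADRO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: ionizable side chains and their acid/base character
_BASIC = {"R": "ARG", "K": "LYS", "H": "HIS"}
_ACIDIC = {"D": "ASP", "E": "GLU", "C": "CYS", "Y": "TYR"}


@dataclass(frozen=True)
class PkaTable:
    """pKa values of ionizable groups, keyed by group label.

    Defaults are the set used for the condensate proteins studied here
    (Tris buffer, pH 8): C-terminus 3.6, ASP 4.0, GLU 4.5, HIS 6.4,
    N-terminus 7.8, CYS 8.14, TYR 9.6, LYS 10.4, ARG 12.5.
    """

    values: Mapping[str, float] = field(
        default_factory=lambda: {
            "CTERM": 3.6,
            "ASP": 4.0,
            "GLU": 4.5,
            "HIS": 6.4,
            "NTERM": 7.8,
            "CYS": 8.14,
            "TYR": 9.6,
            "LYS": 10.4,
            "ARG": 12.5,
        }
    )

    def __post_init__(self) -> None:
        for label, pka in self.values.items():
            if not 0.0 < pka < 14.0:
                raise ValueError(f"pKa for {label} out of (0, 14): {pka}")


@dataclass(frozen=True)
class ProteinSpec:
    """Sequence plus tabulated physical constants for one protein.

    Attributes
    ----------
    name : str
    sequence : str
        One-letter amino-acid string, leader included.
    molar_mass : float
        g/mol.
    molar_volume : float
        cm^3/mol, from tabulated partial specific volumes.
    extinction_coeff : float
        M^-1 cm^-1 at 280 nm.
    """

    name: str
    sequence: str
    molar_mass: float
    molar_volume: float
    extinction_coeff: float

    def __post_init__(self) -> None:
        bad = [(i, a) for i, a in enumerate(self.sequence) if a not in AMINO_ACIDS]
        if bad:
            i, a = bad[0]
            raise ValueError(f"unknown residue code {a!r} at position {i} in {self.name}")
        if self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")
        if self.molar_volume <= 0:
            raise ValueError("molar_volume must be positive")

    @property
    def n_residues(self) -> int:
        """Chain length N (number of monomers, leader included)."""
        return len(self.sequence)


def net_charge(spec: ProteinSpec, ph: float = 8.0, pka: PkaTable | None = None) -> float:
    """Henderson-Hasselbalch net charge in units of e.

    Basic groups contribute ``+1/(1+10^(pH-pKa))``, acidic groups
    ``-1/(1+10^(pKa-pH))``; the free N- and C-termini are counted once each.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH out of (0, 14): {ph}")
    table = (pka or PkaTable()).values
    q = 1.0 / (1.0 + 10.0 ** (ph - table["NTERM"]))
    q -= 1.0 / (1.0 + 10.0 ** (table["CTERM"] - ph))
    for i, a in enumerate(spec.sequence):
        if a in _BASIC:
            q += 1.0 / (1.0 + 10.0 ** (ph - table[_BASIC[a]]))
        elif a in _ACIDIC:
            q -= 1.0 / (1.0 + 10.0 ** (table[_ACIDIC[a]] - ph))
    return q


def lattice_size(spec: ProteinSpec) -> float:
    """Lattice size b in Angstrom: cube root of the molecular volume per residue.

    ``b = (v_p / (N * N_A))^(1/3)`` with v_p the molar volume in cm^3/mol.
    Full precision is returned; note the 3 s.f. value 5.12 A is conventionally
    used as the mean-field lattice input for the proteins studied here.
    """
    if spec.n_residues == 0:
        raise ValueError("empty sequence")
    vol_cm3 = spec.molar_volume / (spec.n_residues * AVOGADRO)  # cm^3 per residue
    return vol_cm3 ** (1.0 / 3.0) * 1e8  # cm -> Angstrom


def molecular_volume(spec: ProteinSpec) -> float:
    """Volume per chain in nm^3: molar volume / Avogadro."""
    return spec.molar_volume / AVOGADRO * 1e21  # cm^3 -> nm^3


# NanoDrop-style spectrophotometer absorbance detection window
ABSORBANCE_LIMITS = (0.08, 30.0)


@dataclass(frozen=True)
class Concentration:
    """Molar concentration with a detection-limit flag."""

    molar: float
    below_limit: bool = False
    above_limit: bool = False

    @property
    def flagged(self) -> bool:
        return self.below_limit or self.above_limit


def concentration_from_absorbance(a280: float, path_cm: float, spec: ProteinSpec) -> Concentration:
    """Beer-Lambert concentration ``c = A / (eps * l)`` in mol/L.

    Absorbances outside the detection window are converted anyway but
    carry a warning flag on the result.
    """
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    lo, hi = ABSORBANCE_LIMITS
    return Concentration(
        molar=a280 / (spec.extinction_coeff * path_cm),
        below_limit=a280 < lo,
        above_limit=a280 > hi,
    )


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("dropsf") / "data" / name))


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def bundled_proteins() -> dict[str, ProteinSpec]:
    """The two bundled Ddx4N constructs (synthetic stand-in sequences).

    Constants (molar mass, molar volume, extinction coefficient) are the
    tabulated values for Ddx4N 1-229 and 1-231. The sequences are a designed
    synthetic stand-in with Ddx4N-like composition and charge patterning
    (the real constructs' sequences are not bundled); their net charges at
    pH 8 are -1.14 e and -2.14 e respectively.
    """
    seqs = load_fasta(_data_path("ddx4n_synthetic.fasta"))
    with open(_data_path("proteins.yaml")) as fh:
        consts = yaml.safe_load(fh)
    out = {}
    for name, c in consts.items():
        out[name] = ProteinSpec(
            name=name,
            sequence=seqs[c["fasta_id"]],
            molar_mass=c["molar_mass_g_mol"],
            molar_volume=c["molar_volume_cm3_mol"],
            extinction_coeff=c["extinction_coeff_M_cm"],
        )
    return out
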