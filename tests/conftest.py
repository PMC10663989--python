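"""Shared fixtures: bundled proteins and cached SCF continuation sweeps."""

import numpy as np
import pytest

from dropsf.scf import SCFConfig, continuation_sweep
from dropsf.sequence_props import bundled_proteins


@pytest.fixture(scope="session")
def proteins():
    return bundled_proteins()


@pytest.fixture(scope="session")
def sweep_234():
    """Full chi descent for N=234 with the exact 0.641 point, profiles kept."""
    base = SCFConfig(chain_length=234, chi=0.741658)
    return continuation_sweep(base, chi_extra=[0.641], keep_profiles=True)


@pytest.fixture(scope="session")
def sweep_236():
    """Full chi descent for N=236 with the exact 0.616 point, profiles kept."""
    base = SCFConfig(chain_length=236, chi=0.741658)
    return continuation_sweep(base, chi_extra=[0.616], keep_profiles=True)


def at_chi(results, chi):
    return min(results, key=lambda r: abs(r.chi - chi))


@pytest.fixture(scope="session")
def scf_229(sweep_234):
    return at_chi(sweep_234, 0.641)


@pytest.fixture(scope="session")
def scf_231(sweep_236):
    return at_chi(sweep_236, 0.616)
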