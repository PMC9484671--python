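"""Shared synthetic fixtures; everything is generated in-process."""

import logging

import numpy as np
import pytest

from aminereact import fixtures as fx
from aminereact.structure_io import place_missing_hydrogens

logging.getLogger("aminereact").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue α-helix with one lysine (site-bearing)."""
    return fx.build_ideal_helix(12, "AAAAAKAAAAAA")


@pytest.fixture(scope="session")
def helix12_protonated(helix12):
    return place_missing_hydrogens(helix12)


@pytest.fixture(scope="session")
def hairpin():
    return fx.build_beta_hairpin()


@pytest.fixture(scope="session")
def lysine_alone():
    """A single lysine residue — the zero-shift pKa reference."""
    return fx.build_peptide("K")


@pytest.fixture()
def rng():
    return np.random.default_rng(20241007)


def random_cluster(rng, n_atoms, spread=4.0, rmin=1.2, rmax=2.2):
    """Random overlapping sphere cluster for SASA oracle comparisons."""
    pos = rng.uniform(-spread, spread, size=(n_atoms, 3))
    radii = rng.uniform(rmin, rmax, size=n_atoms)
    return fx.build_sphere_cluster(pos, radii)
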