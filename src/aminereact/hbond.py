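"""Geometric hydrogen-bond detection and amine donor status.

A bond is recorded for every donor-hydrogen-acceptor triple with a
covalent D-H pair (<= 1.2 Å), donor-acceptor distance within the
cutoff and D-H-A angle at least the angular cutoff.  Donors are N/O
heavy atoms with an attached hydrogen; acceptors are N, O or S;
intra-residue pairs are excluded.  Defaults (D-A <= 3.0 Å,
angle >= 150 deg) follow the common geometric convention; note the
original Baker-Hubbard criterion is phrased on the H...A distance —
this module deliberately adopts the D-A convention.

An amine site "is a donor" when its nitrogen (backbone N for α sites,
NZ for ε sites) donates in at least one detected bond; donation ties
up the lone pair/protons and slows NHS-ester acylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import AmineReactError
from .structure_io import AmineSite, AtomRecord, StructureModel

_COVALENT_DH = 1.2  # Å
_DONOR_ELEMENTS = {"N", "O"}
_ACCEPTOR_ELEMENTS = {"N", "O", "S"}


@dataclass
class HBond:
    """One detected donor-H...acceptor contact."""

    donor: AtomRecord
    hydrogen: AtomRecord
    acceptor: AtomRecord
    distance: float  # D-A, Å
    angle: float  # D-H-A, degrees


def detect_hbonds(model: StructureModel, d_a_cutoff: float = 3.0,
                  angle_cutoff: float = 150.0) -> list[HBond]:
    """All hydrogen bonds satisfying the geometric cutoffs."""
    hydrogens = [a for a in model.atoms if a.element in ("H", "D")]
    if not hydrogens:
        raise AmineReactError(
            "model contains no hydrogens; run place_missing_hydrogens first")
    heavies = [a for a in model.atoms if a.element not in ("H", "D")]
    donors_pool = [a for a in heavies if a.element in _DONOR_ELEMENTS]
    acceptors = [a for a in heavies if a.element in _ACCEPTOR_ELEMENTS]
    if not donors_pool or not acceptors:
        return []

    d_pos = np.array([a.coordinates for a in donors_pool])
    a_pos = np.array([a.coordinates for a in acceptors])
    d_tree = cKDTree(d_pos)
    a_tree = cKDTree(a_pos)

    bonds: list[HBond] = []
    for h in hydrogens:
        # covalently bound donor: nearest N/O within 1.2 Å
        cand = d_tree.query_ball_point(h.coordinates, _COVALENT_DH)
        if not cand:
            continue
        dists = [np.linalg.norm(d_pos[i] - h.coordinates) for i in cand]
        donor = donors_pool[cand[int(np.argmin(dists))]]
        for j in a_tree.query_ball_point(donor.coordinates, d_a_cutoff):
            acc = acceptors[j]
            if acc is donor or acc.residue_key == donor.residue_key:
                continue
            da = float(np.linalg.norm(acc.coordinates - donor.coordinates))
            ang = _angle(donor.coordinates, h.coordinates, acc.coordinates)
            if da <= d_a_cutoff and ang >= angle_cutoff:
                bonds.append(HBond(donor, h, acc, da, ang))
    return bonds


def _angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def is_amine_donor(site: AmineSite, bonds: Sequence[HBond]) -> bool:
    """True iff the site's nitrogen donates in at least one bond."""
    key = (site.residue_key, "NZ" if site.amine_kind == "epsilon" else "N")
    return any((b.donor.residue_key, b.donor.name) == key for b in bonds)
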