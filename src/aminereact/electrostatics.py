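"""Local Coulomb electrostatics at amine nitrogens from PQR charges.

The energy at a target atom i is the bare Coulomb sum

    E_i = sum_j k q_i q_j / (eps r_ij),   k = 332.0637 kcal*Å/(mol*e²)

over all other charged atoms, excluding atoms of the target's own
residue (the quantity is a local-environment energy, not a self
energy).  No distance cutoff is applied.  An amine whose energy
exceeds 100 kcal/mol (strictly) sits in an area of low positive charge
— the favourable case for NHS-ester acylation of the neutral amine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import RunConfig
from .errors import LookupFailure
from .structure_io import AmineSite, ChargedAtom

logger = logging.getLogger(__name__)

COULOMB_K = 332.0637  # kcal * Å / (mol * e^2)
_MIN_DIST = 0.5  # Å; closer pairs are unphysical and skipped


@dataclass
class SiteElectrostatics:
    """Coulomb energy at a site's nitrogen and the derived charge flag."""

    site: AmineSite
    energy: float  # kcal/mol
    low_positive_charge: bool


def atom_coulomb_energy(charged: Sequence[ChargedAtom], target: ChargedAtom,
                        dielectric: float = 1.0,
                        exclude_same_residue: bool = True) -> float:
    """Coulomb energy (kcal/mol) at ``target`` from all other atoms."""
    if not dielectric > 0:
        raise ValueError("dielectric must be positive")
    if not any(a is target for a in charged):
        raise LookupFailure("target atom not present in the charged atom list")
    others = [a for a in charged
              if a is not target
              and not (exclude_same_residue and a.residue_key == target.residue_key)]
    if not others:
        return 0.0
    pos = np.array([a.coordinates for a in others])
    q = np.array([a.partial_charge for a in others])
    r = np.linalg.norm(pos - target.coordinates, axis=1)
    close = r < _MIN_DIST
    if close.any():
        logger.warning("%d atom pair(s) closer than %.1f Å to %s %d skipped",
                       int(close.sum()), _MIN_DIST, target.name, target.serial)
    keep = ~close
    return float(COULOMB_K * target.partial_charge
                 * np.sum(q[keep] / r[keep]) / dielectric)


def find_site_nitrogen(charged: Sequence[ChargedAtom], site: AmineSite,
                       chainless: bool = False) -> ChargedAtom:
    """Locate the site's N (alpha) or NZ (epsilon) among the PQR atoms.

    Matching key is (chain, resnum, icode, atom name); a PQR written in
    the chain-less dialect (``chainless=True``) matches on
    (resnum, icode, atom name) instead.
    """
    want_name = "NZ" if site.amine_kind == "epsilon" else "N"
    for a in charged:
        if a.name != want_name:
            continue
        if a.residue_number != site.residue_number or a.insertion_code != site.insertion_code:
            continue
        if chainless or a.chain_id == site.chain_id:
            return a
    raise LookupFailure(
        f"site {site.site_id}: atom {want_name} not found in PQR "
        f"(residue {site.chain_id}:{site.residue_number}{site.insertion_code})")


def site_charge_flag(charged: Sequence[ChargedAtom], site: AmineSite,
                     config: RunConfig, chainless: bool = False) -> SiteElectrostatics:
    """Energy at the site nitrogen and the low-positive-charge flag.

    The flag is strict: E == threshold exactly is *not* flagged.
    """
    target = find_site_nitrogen(charged, site, chainless=chainless)
    e = atom_coulomb_energy(charged, target, dielectric=config.dielectric,
                            exclude_same_residue=config.exclude_same_residue)
    return SiteElectrostatics(site=site, energy=e,
                              low_positive_charge=e > config.thresholds.charge_threshold)
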