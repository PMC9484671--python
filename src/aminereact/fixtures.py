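"""Synthetic structures and charge systems with known analytic properties.

Everything the test suite scores is generated here, from internal
coordinates or explicit geometry — no downloads.  Builders are
deterministic (an optional seeded coordinate jitter is off by
default):

* ideal peptides/helices from backbone dihedrals (NeRF chain build),
* an antiparallel two-strand sheet with proper backbone H-bond registry,
* pseudo-atom sphere clusters for closed-form SASA checks (isolated
  sphere, two-sphere overlap, a fully enclosing icosahedral shell and
  a deep cylindrical crevice),
* point-charge systems for Coulomb calibration (the two-unit-charge
  pair at 3.320637 Å is exactly 100 kcal/mol at dielectric 1),
* homodimers built by duplicating a monomer onto a new chain,
* a "buried lysine" protein whose lysine flips to non-reacting at
  large probe radius.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import AmineReactError
from .structure_io import (AtomRecord, ChargedAtom, StructureModel, write_pdb,
                           write_pqr)
from .sasa import vdw_radius

# --- internal-coordinate machinery -----------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1u = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to c with angle(b,c,D) and dihedral(a,b,c,D).

    Angles in degrees.  Standard NeRF construction.
    """
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear reference frame: pick any perpendicular
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# side-chain internal coordinates: atom -> (ref atoms, bond, angle, torsion)
_SIDECHAINS: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    "A": [("CB", ("N", "C", "CA"), 1.53, 110.1, 122.6)],
    "G": [],
    "S": [("CB", ("N", "C", "CA"), 1.53, 110.1, 122.6),
          ("OG", ("N", "CA", "CB"), 1.42, 111.0, 180.0)],
    "K": [("CB", ("N", "C", "CA"), 1.53, 110.1, 122.6),
          ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
          ("CE", ("CB", "CG", "CD"), 1.52, 111.0, 180.0),
          ("NZ", ("CG", "CD", "CE"), 1.47, 110.0, 180.0)],
    "D": [("CB", ("N", "C", "CA"), 1.53, 110.1, 122.6),
          ("CG", ("N", "CA", "CB"), 1.52, 113.0, 180.0),
          ("OD1", ("CA", "CB", "CG"), 1.25, 119.0, 0.0),
          ("OD2", ("CA", "CB", "CG"), 1.25, 119.0, 180.0)],
    "E": [("CB", ("N", "C", "CA"), 1.53, 110.1, 122.6),
          ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 113.0, 180.0),
          ("OE1", ("CB", "CG", "CD"), 1.25, 119.0, 0.0),
          ("OE2", ("CB", "CG", "CD"), 1.25, 119.0, 180.0)],
    "P": [("CB", ("N", "C", "CA"), 1.53, 103.0, 115.0),
          ("CG", ("N", "CA", "CB"), 1.50, 104.0, 30.0),
          ("CD", ("CA", "CB", "CG"), 1.51, 104.0, -35.0)],
    "R": [("CB", ("N", "C", "CA"), 1.53, 110.1, 122.6),
          ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
          ("CD", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
          ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
          ("CZ", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
          ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
          ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0)],
}

_THREE = {"A": "ALA", "G": "GLY", "S": "SER", "K": "LYS", "D": "ASP",
          "E": "GLU", "R": "ARG", "P": "PRO"}

# backbone geometry (Å / degrees)
_B_NCA, _B_CAC, _B_CN, _B_CO = 1.458, 1.525, 1.329, 1.231
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.8


def build_peptide(sequence: str, phi: float = -57.0, psi: float = -47.0,
                  omega: float = 180.0, chain_id: str = "A",
                  start_number: int = 1, jitter_sigma: float = 0.0,
                  seed: int = 0) -> StructureModel:
    """Ideal polypeptide with uniform backbone dihedrals.

    ``jitter_sigma`` adds seeded isotropic Gaussian noise (Å, <= 0.05
    recommended) for robustness tests; default off.
    """
    bad = [c for c in sequence if c not in _SIDECHAINS]
    if bad:
        raise AmineReactError(f"unsupported residue letter(s) {sorted(set(bad))}; "
                              f"supported: {sorted(_SIDECHAINS)}")
    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, resname: str, resnum: int, pos: np.ndarray,
            element: Optional[str] = None) -> None:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, element or name[0], resname,
                                chain_id, resnum, pos))

    prev: dict[str, np.ndarray] = {}
    for i, letter in enumerate(sequence):
        resname = _THREE[letter]
        resnum = start_number + i
        if i == 0:
            n = np.zeros(3)
            ca = np.array([_B_NCA, 0.0, 0.0])
            ang = np.radians(_A_NCAC)
            c = ca + _B_CAC * np.array([-np.cos(ang), np.sin(ang), 0.0])
        else:
            n = place_atom(prev["N"], prev["CA"], prev["C"], _B_CN, _A_CACN, psi)
            ca = place_atom(prev["CA"], prev["C"], n, _B_NCA, _A_CNCA, omega)
            c = place_atom(prev["C"], n, ca, _B_CAC, _A_NCAC, phi)
        o = place_atom(n, ca, c, _B_CO, _A_CACO, psi + 180.0)
        cur = {"N": n, "CA": ca, "C": c, "O": o}
        add("N", resname, resnum, n, "N")
        add("CA", resname, resnum, ca, "C")
        add("C", resname, resnum, c, "C")
        add("O", resname, resnum, o, "O")
        for name, (r1, r2, r3), bond, angle, tor in _SIDECHAINS[letter]:
            pos = place_atom(cur[r1], cur[r2], cur[r3], bond, angle, tor)
            cur[name] = pos
            add(name, resname, resnum, pos, name[0])
        prev = cur
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        for a in atoms:
            a.coordinates = a.coordinates + rng.normal(0, jitter_sigma, 3)
    return StructureModel(atoms, provenance={"source": "fixtures.build_peptide"})


def build_ideal_helix(n: int, sequence: Optional[str] = None,
                      jitter_sigma: float = 0.0, seed: int = 0) -> StructureModel:
    """Ideal α-helix (φ=-57°, ψ=-47°, ω=180°), n >= 4 residues."""
    if n < 4:
        raise AmineReactError("an ideal helix needs n >= 4 residues")
    seq = sequence or "A" * n
    if len(seq) != n:
        raise AmineReactError("sequence length must equal n")
    return build_peptide(seq, phi=-57.0, psi=-47.0, jitter_sigma=jitter_sigma,
                         seed=seed)


# frozen rigid transform (rotation vector + translation) that places the
# duplicate of a 6-residue (phi=-139, psi=135) strand antiparallel to the
# original with Kabsch-Sander energies ~ -2 kcal/mol on the bonded pairs
_HAIRPIN6_TRANSFORM = np.array([-0.44099322, 0.96689764, -3.01081552,
                                -0.8891611, 1.301471, -4.21026467])


def build_beta_hairpin(n_per_strand: int = 6) -> StructureModel:
    """Two antiparallel β-strands (chains A, B) with inter-strand H-bonds.

    Strand B is a rigid copy of strand A placed so that the narrow
    (bonded) residue pairs i / n+1-i form backbone N-H...O=C bonds in
    both directions.  For the default length the placing transform is a
    frozen constant; other lengths run a deterministic rigid-body
    refinement of the pairs' Kabsch-Sander energies.
    """
    a = build_peptide("A" * n_per_strand, phi=-139.0, psi=135.0, chain_id="A")
    coords = a.coordinates()
    centroid = coords.mean(axis=0)
    if n_per_strand == 6:
        x = _HAIRPIN6_TRANSFORM
    else:
        x = _refine_hairpin_transform(a, coords, centroid, n_per_strand)
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(x[:3]).as_matrix()
    shifted = (coords - centroid) @ rot.T + centroid + x[3:]

    atoms = list(a.atoms)
    serial = len(atoms)
    for at, pos in zip(a.atoms, shifted):
        serial += 1
        atoms.append(AtomRecord(serial, at.name, at.element, at.residue_name,
                                "B", at.residue_number, pos))
    return StructureModel(atoms, provenance={"source": "fixtures.build_beta_hairpin"})


def _refine_hairpin_transform(a: StructureModel, coords: np.ndarray,
                              centroid: np.ndarray, n: int) -> np.ndarray:
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    from .secondary_structure import _backbone, _ks_energy

    def make(newc):
        atoms = list(a.atoms)
        serial = len(atoms)
        for at, pos in zip(a.atoms, newc):
            serial += 1
            atoms.append(AtomRecord(serial, at.name, at.element, at.residue_name,
                                    "B", at.residue_number, pos))
        return StructureModel(atoms)

    def transform(x):
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return (coords - centroid) @ rot.T + centroid + x[3:]

    want = [(i - 1, (n - 1) + (n + 1 - i)) for i in range(1, n + 1) if i % 2 == 1]

    def cost(x):
        newc = transform(x)
        bb = _backbone(make(newc))
        c = 0.0
        for bi, bj in want:
            for d_, a_ in ((bi, bj), (bj, bi)):
                if bb[d_].h is None:
                    c += 3.0
                else:
                    c += _ks_energy(bb[d_].n, bb[d_].h, bb[a_].c, bb[a_].o)
        d = np.linalg.norm(coords[:, None, :] - newc[None, :, :], axis=2)
        return c + np.sum(np.clip(2.7 - d, 0, None) ** 2) * 20.0

    rng = np.random.default_rng(0)
    best = None
    for _ in range(40):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        t = rng.normal(scale=3, size=3) + np.array([0, 4.8, 0]) * rng.choice([-1, 1])
        res = minimize(cost, np.concatenate([v * np.pi, t]), method="Nelder-Mead",
                       options={"maxiter": 6000, "xatol": 1e-9, "fatol": 1e-13})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


# --- pseudo-atom clusters ---------------------------------------------------


def build_sphere_cluster(positions: Sequence[Sequence[float]],
                         radii: Sequence[float]) -> tuple[StructureModel, np.ndarray]:
    """Pseudo-atom cluster for SASA tests; returns (model, radii array)."""
    positions = np.asarray(positions, float)
    radii = np.asarray(radii, float)
    if len(positions) != len(radii) or len(positions) == 0:
        raise AmineReactError("need equal, nonzero numbers of positions and radii")
    atoms = [AtomRecord(i + 1, "C", "C", "SPH", "A", i + 1, p)
             for i, p in enumerate(positions)]
    return StructureModel(atoms, provenance={"source": "fixtures.sphere_cluster"}), radii


def build_enclosing_shell(inner_radius: float = 1.5, shell_radius: float = 3.0,
                          distance: float = 4.0) -> tuple[StructureModel, np.ndarray]:
    """A central atom fully enclosed by a 12-atom icosahedral shell."""
    g = (1.0 + 5.0 ** 0.5) / 2.0
    verts = []
    for s1 in (1, -1):
        for s2 in (1, -1):
            verts += [(0, s1, s2 * g), (s1, s2 * g, 0), (s2 * g, 0, s1)]
    verts = np.array(verts, float)
    verts = verts / np.linalg.norm(verts[0]) * distance
    positions = np.vstack([[0.0, 0.0, 0.0], verts])
    radii = np.array([inner_radius] + [shell_radius] * 12)
    return build_sphere_cluster(positions, radii)


def build_crevice(wall_radius: float = 4.5, n_wall: int = 12,
                  heights: Sequence[float] = (2.0, 4.0, 6.0, 8.0, 10.0)
                  ) -> tuple[StructureModel, np.ndarray]:
    """A target atom at the bottom of a deep open cylinder.

    The target (index 0) is exposed to a small probe through the top
    opening but fully sealed for probes larger than the opening.
    """
    pts = [[0.0, 0.0, 0.0]]
    for h in heights:
        for k in range(n_wall):
            ang = 2 * np.pi * k / n_wall
            pts.append([wall_radius * np.cos(ang), wall_radius * np.sin(ang), h])
    # bottom cap
    for k in range(8):
        ang = 2 * np.pi * k / 8
        pts.append([3.0 * np.cos(ang), 3.0 * np.sin(ang), -2.0])
    pts.append([0.0, 0.0, -3.6])
    radii = np.full(len(pts), 1.8)
    return build_sphere_cluster(pts, radii)


# --- charge systems ---------------------------------------------------------

#: distance at which two unit charges give exactly 100 kcal/mol at eps=1
CALIBRATION_DISTANCE = 3.320637


def build_charge_system(positions: Sequence[Sequence[float]],
                        charges: Sequence[float],
                        radii: Optional[Sequence[float]] = None,
                        one_residue_per_atom: bool = True) -> list[ChargedAtom]:
    """Point charges as ChargedAtoms (each its own residue by default)."""
    positions = np.asarray(positions, float)
    charges = np.asarray(charges, float)
    if len(positions) != len(charges) or len(positions) == 0:
        raise AmineReactError("need equal, nonzero numbers of positions and charges")
    radii = np.asarray(radii, float) if radii is not None else np.full(len(charges), 1.5)
    out = []
    for i, (p, q, r) in enumerate(zip(positions, charges, radii)):
        resnum = i + 1 if one_residue_per_atom else 1
        out.append(ChargedAtom(i + 1, "Q", "X", "CHG", "A", resnum, p,
                               partial_charge=float(q), radius=float(r)))
    return out


def build_calibration_pair() -> list[ChargedAtom]:
    """Two +1 e charges 3.320637 Å apart: 100.0 kcal/mol at eps=1."""
    return build_charge_system([[0.0, 0.0, 0.0], [CALIBRATION_DISTANCE, 0.0, 0.0]],
                               [1.0, 1.0])


def build_symmetric_cancellation(target_charge: float = 1.0) -> list[ChargedAtom]:
    """A target charge surrounded by mirror-symmetric ± pairs: E = 0."""
    pos = [[0.0, 0.0, 0.0],
           [4.0, 0.0, 0.0], [-4.0, 0.0, 0.0],
           [0.0, 4.0, 0.0], [0.0, -4.0, 0.0]]
    chg = [target_charge, 0.7, -0.7, -0.4, 0.4]
    return build_charge_system(pos, chg)


# --- assemblies -------------------------------------------------------------


def build_homodimer(monomer: StructureModel,
                    displacement: Sequence[float]) -> StructureModel:
    """Duplicate the monomer onto the next free chain id, displaced."""
    displacement = np.asarray(displacement, float)
    used = set(monomer.chains)
    free = [c for c in string.ascii_uppercase if c not in used]
    if not free:
        raise AmineReactError("no free chain id for the duplicate")
    new_chain = free[0]
    atoms = list(monomer.atoms)
    serial = max(a.serial for a in atoms)
    for a in monomer.atoms:
        serial += 1
        atoms.append(AtomRecord(serial, a.name, a.element, a.residue_name,
                                new_chain, a.residue_number,
                                a.coordinates + displacement,
                                a.insertion_code, a.is_hetero))
    return StructureModel(atoms, provenance={"source": "fixtures.build_homodimer"})


def build_buried_lysine_protein(pocket_radius: float = 12.0,
                                wall_spacing: float = 3.0) -> StructureModel:
    """A lysine at the bottom of a glycine-walled cylindrical pocket.

    At the default 4.2 Å probe the lysine residue is exposed through
    the pocket opening (residue ESA well above the 50 Å² branch); at
    large probe radii (>~15 Å) the opening seals, its ESA collapses to
    zero and the site flips to non-reacting.
    """
    core = build_peptide("K")
    coords = core.coordinates()
    center = coords.mean(axis=0)
    atoms = [AtomRecord(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                        a.residue_number, a.coordinates - center)
             for a in core.atoms]
    serial = len(atoms)
    resnum = 10
    z_levels = np.arange(2.0, 2.0 + 5 * wall_spacing, wall_spacing)
    for zi, z in enumerate(z_levels):
        for k in range(16):
            ang = 2 * np.pi * k / 16 + (0.2 * zi)
            p = np.array([pocket_radius * np.cos(ang),
                          pocket_radius * np.sin(ang), z])
            resnum += 1
            for name, off in (("N", (0, 0, 0)), ("CA", (1.3, 0, 0)),
                              ("C", (0, 1.3, 0)), ("O", (0, 0, 1.3))):
                serial += 1
                atoms.append(AtomRecord(serial, name, name[0], "GLY", "A",
                                        resnum, p + np.array(off, float)))
    # bottom cap under the lysine
    for k in range(10):
        ang = 2 * np.pi * k / 10
        p = np.array([4.5 * np.cos(ang), 4.5 * np.sin(ang), -4.5])
        resnum += 1
        for name, off in (("N", (0, 0, 0)), ("CA", (1.3, 0, 0)),
                          ("C", (0, 1.3, 0)), ("O", (0, 0, 1.3))):
            serial += 1
            atoms.append(AtomRecord(serial, name, name[0], "GLY", "A",
                                    resnum, p + np.array(off, float)))
    atoms.append(AtomRecord(serial + 1, "CA", "C", "GLY", "A", resnum + 1,
                            np.array([0.0, 0.0, -5.8])))
    return StructureModel(atoms, provenance={"source": "fixtures.buried_lysine"})


# --- PQR generation for pipeline fixtures ----------------------------------

_FORMAL_CHARGES = {("LYS", "NZ"): 1.0, ("ARG", "CZ"): 0.64,
                   ("ARG", "NH1"): 0.18, ("ARG", "NH2"): 0.18,
                   ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
                   ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5}


def model_to_pqr(model: StructureModel, scheme: str = "formal"
                 ) -> list[ChargedAtom]:
    """Charged-atom list for a synthetic model (formal-charge scheme).

    Heavy atoms only; side-chain titratable groups carry their formal
    charges, everything else is neutral.  This stands in for a
    force-field PQR when scoring synthetic fixtures.
    """
    if scheme != "formal":
        raise AmineReactError(f"unknown charge scheme {scheme!r}")
    out: list[ChargedAtom] = []
    for a in model.atoms:
        if a.element in ("H", "D"):
            continue
        q = _FORMAL_CHARGES.get((a.residue_name, a.name), 0.0)
        out.append(ChargedAtom(a.serial, a.name, a.element, a.residue_name,
                               a.chain_id, a.residue_number, a.coordinates.copy(),
                               a.insertion_code, a.is_hetero,
                               partial_charge=q, radius=max(vdw_radius(a), 1.0)))
    return out


def write_fixture(model_or_atoms, path: str | Path) -> None:
    """Write a fixture as PDB (StructureModel) or PQR (ChargedAtom list)."""
    path = Path(path)
    if isinstance(model_or_atoms, StructureModel):
        write_pdb(model_or_atoms, path)
    else:
        write_pqr(model_or_atoms, path)
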