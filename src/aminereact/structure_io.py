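"""Read, clean and subset PDB/PQR structures; enumerate amine sites.

The in-memory model is a flat, ordered list of atom records grouped on
demand into residues.  Residue identity is (chain, number, insertion
code) and residue numbers are kept verbatim from the input file — no
renumbering.  Only the first model of a multi-model (NMR) file is read
and alternate locations are collapsed to the highest-occupancy
conformer (ties resolved toward altloc "A"), so one conformation is
scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .errors import AmineReactError, EmptyStructureError, LookupFailure, ParseError

logger = logging.getLogger(__name__)

#: 3-letter codes treated as standard amino acids.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


@dataclass
class AtomRecord:
    """One atom of the structure, as read from the file."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray
    insertion_code: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial} ({self.name}): bad coordinates")
        self.name = self.name.strip()

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class ChargedAtom(AtomRecord):
    """Atom with a partial charge (e) and radius (Å), from a PQR file."""

    partial_charge: float = 0.0
    radius: float = 1.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if not self.radius > 0:
            raise ValueError(f"atom {self.serial} ({self.name}): radius must be > 0")
        if not np.isfinite(self.partial_charge):
            raise ValueError(f"atom {self.serial} ({self.name}): non-finite charge")


@dataclass
class ResidueView:
    """All atoms sharing one (chain, number, icode) identity."""

    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[AtomRecord]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA and not any(a.is_hetero for a in self.atoms)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """Ordered atom list plus provenance of how it was produced."""

    atoms: list[AtomRecord]
    provenance: dict = field(default_factory=dict)

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def residues(self) -> list[ResidueView]:
        out: list[ResidueView] = []
        current: Optional[ResidueView] = None
        for a in self.atoms:
            if current is None or current.key != a.residue_key:
                current = ResidueView(a.chain_id, a.residue_number, a.insertion_code,
                                      a.residue_name, [])
                out.append(current)
            current.atoms.append(a)
        return out

    def residue(self, chain_id: str, number: int, icode: str = "") -> ResidueView:
        for r in self.residues():
            if r.key == (chain_id, number, icode):
                return r
        raise LookupFailure(f"residue {chain_id}:{number}{icode} not in model")

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.coordinates for a in self.atoms])


@dataclass(frozen=True)
class AmineSite:
    """One α- (chain N-terminus) or ε- (lysine NZ) amino group."""

    site_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    amine_kind: str  # "alpha" | "epsilon"
    nitrogen: AtomRecord

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


def parse_pdb(path: str | Path, keep_hetero: bool = True) -> StructureModel:
    """Parse a PDB file into a StructureModel.

    First model only; alternate locations collapsed to the
    highest-occupancy conformer (tie → altloc "A"); ANISOU/TER ignored.
    HETATM records are kept but flagged; pass them through
    :func:`clean_structure` to drop waters and (optionally) hetero
    groups.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as e:  # gemmi names the offending line
        raise ParseError(f"{path}: {e}") from e
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            # collapse altlocs per atom name: highest occupancy, tie -> 'A'
            by_name: dict[str, list] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                best = sorted(group, key=lambda a: (-a.occ, a.altloc or ""))[0]
                atoms.append(AtomRecord(
                    serial=best.serial,
                    name=name,
                    element=best.element.name.upper(),
                    residue_name=res.name,
                    chain_id=(chain.name or "A"),
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    coordinates=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    is_hetero=het,
                ))
    if not any(not a.is_hetero for a in atoms):
        # a file of only HETATMs (e.g. waters) has nothing to score
        if not atoms:
            raise EmptyStructureError(f"{path}: no ATOM records")
    m = StructureModel(atoms, provenance={"source": str(path), "steps": ["parse_pdb"]})
    logger.info("parse_pdb: %s -> %d atoms, chains %s", path.name, len(atoms), m.chains)
    return m


def parse_pqr(path: str | Path) -> list[ChargedAtom]:
    """Parse a whitespace-delimited PQR file.

    Accepts both dialects (with and without the chain column); the
    chain-less dialect assigns chain "A".  Fields per ATOM/HETATM line:
    record, serial, name, resname, [chain], resnum[icode], x, y, z,
    charge, radius.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    out: list[ChargedAtom] = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        tok = line.split()
        if not tok or tok[0] not in ("ATOM", "HETATM"):
            continue
        rec = tok[0]
        # chain column present iff token 4 is a single letter and token 5
        # starts the residue number
        has_chain = len(tok) >= 11 and len(tok[4]) == 1 and tok[4].isalpha()
        want = 11 if has_chain else 10
        if len(tok) < want:
            raise ParseError(f"{path}:{lineno}: expected {want} fields, got {len(tok)}")
        chain = tok[4] if has_chain else "A"
        resnum_tok = tok[5] if has_chain else tok[4]
        icode = ""
        if resnum_tok and resnum_tok[-1].isalpha():
            icode = resnum_tok[-1]
            resnum_tok = resnum_tok[:-1]
        idx = 6 if has_chain else 5
        try:
            resnum = int(resnum_tok)
            x, y, z, q, r = (float(t) for t in tok[idx:idx + 5])
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: non-numeric field ({e})") from e
        try:
            out.append(ChargedAtom(
                serial=int(tok[1]), name=tok[2], element=_element_of(tok[2]),
                residue_name=tok[3], chain_id=chain, residue_number=resnum,
                insertion_code=icode, coordinates=np.array([x, y, z]),
                is_hetero=(rec == "HETATM"),
                partial_charge=q, radius=r,
            ))
        except ValueError as e:
            raise ParseError(f"{path}:{lineno}: {e}") from e
    if not out:
        raise ParseError(f"{path}: no ATOM records")
    for chain in {a.chain_id for a in out}:
        total = sum(a.partial_charge for a in out if a.chain_id == chain)
        logger.info("parse_pqr: chain %s total charge %+.3f e", chain, total)
    return out


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    for ch in name:
        if ch.isalpha():
            first = ch
            break
    else:
        return "X"
    if name[:2].upper() in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return name[:2].upper()
    return first.upper()


def clean_structure(model: StructureModel, keep_hetero: bool = False) -> StructureModel:
    """Drop waters (always) and hetero groups (unless ``keep_hetero``)."""
    kept: list[AtomRecord] = []
    n_water = n_het = 0
    for a in model.atoms:
        if a.residue_name in WATER_NAMES:
            n_water += 1
            continue
        if a.is_hetero and not keep_hetero:
            n_het += 1
            continue
        kept.append(a)
    logger.info("clean_structure: removed %d water and %d hetero atoms", n_water, n_het)
    if not kept:
        raise EmptyStructureError("no atoms remain after cleaning")
    prov = dict(model.provenance)
    prov["steps"] = prov.get("steps", []) + [f"clean(keep_hetero={keep_hetero})"]
    return StructureModel(kept, prov)


def select_assembly(model: StructureModel, chains: Iterable[str]) -> StructureModel:
    """Restrict the model to the given chains (e.g. one sub-unit of a dimer).

    Downstream parameters must be recomputed on the subset; nothing is
    cached across subsets.
    """
    wanted = list(chains)
    available = model.chains
    missing = [c for c in wanted if c not in available]
    if missing:
        raise LookupFailure(
            f"unknown chain(s) {missing}; available chains: {available}")
    kept = [a for a in model.atoms if a.chain_id in wanted]
    prov = dict(model.provenance)
    prov["steps"] = prov.get("steps", []) + [f"select_assembly({','.join(wanted)})"]
    return StructureModel(kept, prov)


def enumerate_amine_sites(model: StructureModel) -> list[AmineSite]:
    """List every α- and ε-amino site in deterministic order.

    One ε site per lysine (its NZ), one α site per chain at the chain's
    first standard residue (its backbone N).  An N-terminal lysine
    yields both.  Order: chain, residue number, α before ε.
    """
    sites: list[AmineSite] = []
    residues = [r for r in model.residues() if r.is_standard]
    by_chain: dict[str, list[ResidueView]] = {}
    for r in residues:
        by_chain.setdefault(r.chain_id, []).append(r)
    for chain_id in model.chains:
        chain_res = by_chain.get(chain_id, [])
        if not chain_res:
            logger.warning("chain %s has no standard residues; skipped", chain_id)
            continue
        first = chain_res[0]
        n_atom = first.atom("N")
        if n_atom is None:
            logger.warning("chain %s first residue lacks backbone N; no alpha site",
                           chain_id)
        else:
            sites.append(_mk_site(first, "alpha", n_atom))
        for r in chain_res:
            if r.name != "LYS":
                continue
            nz = r.atom("NZ")
            if nz is None:
                logger.warning("LYS %s:%d%s lacks NZ; epsilon site skipped",
                               r.chain_id, r.number, r.icode)
                continue
            sites.append(_mk_site(r, "epsilon", nz))
    sites.sort(key=lambda s: (model.chains.index(s.chain_id), s.residue_number,
                              s.insertion_code, 0 if s.amine_kind == "alpha" else 1))
    return sites


def _mk_site(res: ResidueView, kind: str, nitrogen: AtomRecord) -> AmineSite:
    sid = f"{res.chain_id}:{res.number}{res.icode}:{kind}"
    return AmineSite(site_id=sid, chain_id=res.chain_id, residue_number=res.number,
                     insertion_code=res.icode, residue_name=res.name,
                     amine_kind=kind, nitrogen=nitrogen)


# --- hydrogen placement -----------------------------------------------------

_NH_LENGTH = 1.01  # Å


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def place_missing_hydrogens(model: StructureModel) -> StructureModel:
    """Add backbone amide hydrogens and lysine NZ hydrogens geometrically.

    The amide H is placed 1.01 Å from N along the bisector of the
    N→C(prev) and N→O(prev) directions — i.e. anti to the preceding
    carbonyl, in its plane (the classic coordinate-only estimate).
    Lysine NZ receives three tetrahedral hydrogens at 1.01 Å staggered
    against CD.  Prolines get no amide H; existing hydrogens are left
    untouched; residues whose preceding residue lacks C or O are
    skipped with a warning.  N-terminal amines are not protonated by
    this rule (no preceding carbonyl to define the geometry).
    """
    atoms = list(model.atoms)
    serial = max((a.serial for a in atoms), default=0)
    new_atoms: list[tuple[int, AtomRecord]] = []  # (insert position, atom)
    residues = model.residues()
    index_of_atom = {id(a): i for i, a in enumerate(atoms)}

    for i, res in enumerate(residues):
        if not res.is_standard:
            continue
        # backbone amide H
        if res.name != "PRO" and res.atom("H") is None and res.atom("N") is not None:
            prev = residues[i - 1] if i > 0 else None
            if prev is None or prev.chain_id != res.chain_id:
                continue_amide = False
            else:
                continue_amide = prev.atom("C") is not None and prev.atom("O") is not None
            if continue_amide:
                n = res.atom("N").coordinates
                c_prev = prev.atom("C").coordinates
                o_prev = prev.atom("O").coordinates
                try:
                    direction = _unit(_unit(n - c_prev) + _unit(n - o_prev))
                except ValueError:
                    logger.warning("degenerate geometry at %s:%d; amide H skipped",
                                   res.chain_id, res.number)
                    direction = None
                if direction is not None:
                    serial += 1
                    h = AtomRecord(serial, "H", "H", res.name, res.chain_id,
                                   res.number, n + _NH_LENGTH * direction,
                                   res.icode, False)
                    new_atoms.append((index_of_atom[id(res.atoms[-1])], h))
            elif prev is not None and prev.chain_id == res.chain_id:
                logger.warning("missing C/O in preceding residue of %s:%d%s; "
                               "amide H skipped", res.chain_id, res.number, res.icode)
        # lysine NZ hydrogens
        if res.name == "LYS" and res.atom("NZ") is not None:
            if any(a.name.startswith("HZ") for a in res.atoms):
                continue
            ce, cd = res.atom("CE"), res.atom("CD")
            if ce is None or cd is None:
                logger.warning("LYS %s:%d lacks CE/CD; NZ hydrogens skipped",
                               res.chain_id, res.number)
                continue
            for k, pos in enumerate(_tetrahedral_h(res.atom("NZ").coordinates,
                                                   ce.coordinates, cd.coordinates), 1):
                serial += 1
                h = AtomRecord(serial, f"HZ{k}", "H", res.name, res.chain_id,
                               res.number, pos, res.icode, False)
                new_atoms.append((index_of_atom[id(res.atoms[-1])], h))

    if not new_atoms:
        out = atoms
    else:
        out = []
        pending = sorted(new_atoms, key=lambda t: t[0])
        j = 0
        for i, a in enumerate(atoms):
            out.append(a)
            while j < len(pending) and pending[j][0] == i:
                out.append(pending[j][1])
                j += 1
    prov = dict(model.provenance)
    prov["steps"] = prov.get("steps", []) + [f"protonate(+{len(new_atoms)}H)"]
    logger.info("place_missing_hydrogens: added %d hydrogens", len(new_atoms))
    return StructureModel(out, prov)


def _tetrahedral_h(nz: np.ndarray, ce: np.ndarray, cd: np.ndarray) -> list[np.ndarray]:
    """Three NH3+ hydrogens on NZ, staggered relative to CD."""
    axis = _unit(nz - ce)
    ref = cd - ce
    perp = ref - np.dot(ref, axis) * axis
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(axis, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(axis, np.array([0.0, 1.0, 0.0]))
    u = _unit(perp)
    v = np.cross(axis, u)
    out = []
    theta = np.deg2rad(180.0 - 109.47)  # angle between CE->NZ axis and N-H
    for k in range(3):
        phi = np.deg2rad(60.0 + 120.0 * k)  # staggered vs CD
        d = (np.cos(theta) * axis
             + np.sin(theta) * (np.cos(phi) * u + np.sin(phi) * v))
        out.append(nz + _NH_LENGTH * d)
    return out


# --- writing ----------------------------------------------------------------

def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB (coordinates in cols 31-54)."""
    lines = []
    for a in model.atoms:
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        x, y, z = a.coordinates
        lines.append(
            f"{rec}{a.serial % 100000:5d} {name:<4s}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id[:1]}{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pqr(atoms: Sequence[ChargedAtom], path: str | Path,
              with_chain: bool = True) -> None:
    """Write charged atoms in the whitespace PQR dialect."""
    lines = []
    for a in atoms:
        x, y, z = a.coordinates
        chain = f"{a.chain_id} " if with_chain else ""
        lines.append(
            f"ATOM {a.serial} {a.name} {a.residue_name} {chain}"
            f"{a.residue_number}{a.insertion_code} "
            f"{x:.3f} {y:.3f} {z:.3f} {a.partial_charge:.4f} {a.radius:.4f}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
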