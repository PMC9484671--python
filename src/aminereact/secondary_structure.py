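"""Kabsch-Sander secondary structure assignment (8-state, collapsed to 3).

Backbone hydrogen bonds are scored with the classic electrostatic
model,

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol,

a bond being recorded when E < -0.5 kcal/mol (at most the two
lowest-energy acceptors per donor).  n-turns (i -> i+3/4/5), the
minimal-helix rule (two consecutive turns), bridge/ladder detection,
turns and bends then yield the 8 classes {H,G,I,E,B,T,S,-}, collapsed
as {H,G,I} -> helix, {E,B} -> strand, {T,S,-} -> coil.

When a residue lacks a placed amide hydrogen the classic coordinate
estimate is used: H = N + 1.01 Å along the bisector of N->C(prev) and
N->O(prev).  Priority when classes compete on one residue:
H > E > G > I > B > T > S > '-'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import ResidueView, StructureModel

logger = logging.getLogger(__name__)

_KS_COUPLING = 0.084 * 332.0  # kcal/mol * Å
HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_MIN_DIST = 0.5  # Å; closer -> clamp energy


@dataclass
class KabschSanderBond:
    """Backbone N-H(donor) ... O=C(acceptor) bond with its K-S energy."""

    donor: int  # index into the backbone residue list
    acceptor: int
    energy: float  # kcal/mol


@dataclass
class SecondaryStructure:
    """Per-residue 8-state and 3-state assignments, in residue order."""

    residue_keys: list[tuple[str, int, str]]
    ss8: list[str]

    @property
    def ss3(self) -> list[str]:
        return [collapse_ss8(c) for c in self.ss8]

    def ss3_of(self, key: tuple[str, int, str]) -> str:
        try:
            return self.ss3[self.residue_keys.index(key)]
        except ValueError:
            return "coil"

    def ss8_of(self, key: tuple[str, int, str]) -> str:
        try:
            return self.ss8[self.residue_keys.index(key)]
        except ValueError:
            return "-"


def collapse_ss8(c: str) -> str:
    if c in "HGI":
        return "helix"
    if c in "EB":
        return "strand"
    return "coil"


@dataclass
class _BBRes:
    key: tuple[str, int, str]
    chain: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    h: Optional[np.ndarray]
    is_pro: bool
    chain_first: bool


def _backbone(model: StructureModel) -> list[_BBRes]:
    out: list[_BBRes] = []
    prev: Optional[ResidueView] = None
    for res in model.residues():
        if not res.is_standard:
            prev = None
            continue
        atoms = {nm: res.atom(nm) for nm in ("N", "CA", "C", "O")}
        if any(v is None for v in atoms.values()):
            logger.warning("residue %s:%d%s missing backbone atoms; skipped in "
                           "secondary structure", res.chain_id, res.number, res.icode)
            prev = None
            continue
        chain_first = prev is None or prev.chain_id != res.chain_id
        h_atom = res.atom("H")
        h = h_atom.coordinates if h_atom is not None else None
        if h is None and not chain_first and res.name != "PRO":
            pc, po = prev.atom("C"), prev.atom("O")
            if pc is not None and po is not None:
                n = atoms["N"].coordinates
                d1 = n - pc.coordinates
                d2 = n - po.coordinates
                d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
                h = n + 1.01 * d / np.linalg.norm(d)
        out.append(_BBRes(key=res.key, chain=res.chain_id,
                          n=atoms["N"].coordinates, ca=atoms["CA"].coordinates,
                          c=atoms["C"].coordinates, o=atoms["O"].coordinates,
                          h=h, is_pro=(res.name == "PRO"), chain_first=chain_first))
        prev = res
    return out


def kabsch_sander_hbonds(model: StructureModel) -> list[KabschSanderBond]:
    """All backbone H-bonds with E < -0.5 kcal/mol (<= 2 acceptors/donor)."""
    bb = _backbone(model)
    return _bonds_for(bb)


def _peptide_bonded_next(bb: Sequence[_BBRes]) -> list[bool]:
    """True at i when residue i+1 is covalently continuous with i."""
    out = []
    for i in range(len(bb) - 1):
        nxt = bb[i + 1]
        out.append(bb[i].chain == nxt.chain and not nxt.chain_first
                   and np.linalg.norm(nxt.n - bb[i].c) < 2.5)
    out.append(False)
    return out


def _bonds_for(bb: Sequence[_BBRes]) -> list[KabschSanderBond]:
    bonds: list[KabschSanderBond] = []
    linked = _peptide_bonded_next(bb)
    for i, don in enumerate(bb):
        if don.is_pro or don.h is None:
            continue
        cand: list[KabschSanderBond] = []
        for j, acc in enumerate(bb):
            # self and peptide-bonded neighbours excluded: a residue's N-H
            # cannot hydrogen-bond its own or its covalent neighbours' C=O
            if j == i or (j == i + 1 and linked[i]) or (j == i - 1 and linked[j]):
                continue
            e = _ks_energy(don.n, don.h, acc.c, acc.o)
            if e < HBOND_ENERGY_CUTOFF:
                cand.append(KabschSanderBond(i, j, e))
        cand.sort(key=lambda b: b.energy)
        bonds.extend(cand[:2])
    return bonds


def _ks_energy(n: np.ndarray, h: np.ndarray, c: np.ndarray, o: np.ndarray) -> float:
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
        return -9.9  # clashing backbone; clamp as in the classic method
    return float(_KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def assign_ss(model: StructureModel) -> SecondaryStructure:
    """8-state assignment for every standard residue with full backbone."""
    bb = _backbone(model)
    n = len(bb)
    bonds = _bonds_for(bb)
    hb = {(b.donor, b.acceptor) for b in bonds}
    linked = _peptide_bonded_next(bb)

    def bonded(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in hb

    def contiguous(i: int, j: int) -> bool:
        return all(linked[k] for k in range(i, j))

    # n-turns: residue i starts an n-turn when N-H(i+n) bonds C=O(i)
    turn = {3: np.zeros(n, bool), 4: np.zeros(n, bool), 5: np.zeros(n, bool)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if contiguous(i, i + k) and bonded(i + k, i):
                turn[k][i] = True

    # bridges
    para = np.zeros(n, bool)
    anti = np.zeros(n, bool)
    bridge_partner: dict[int, list[int]] = {}
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            if abs(i - j) < 3:
                continue
            p = (bonded(j, i - 1) and bonded(i + 1, j)) or \
                (bonded(i, j - 1) and bonded(j + 1, i))
            a = (bonded(i, j) and bonded(j, i)) or \
                (bonded(j + 1, i - 1) and bonded(i + 1, j - 1))
            if p or a:
                para[i] |= p
                anti[i] |= a
                bridge_partner.setdefault(i, []).append(j)

    ss8 = ["-"] * n

    def claim(i: int, c: str) -> None:
        # priority H > E > G > I > B > T > S > '-'
        order = {"H": 7, "E": 6, "G": 5, "I": 4, "B": 3, "T": 2, "S": 1, "-": 0}
        if order[c] > order[ss8[i]]:
            ss8[i] = c

    # minimal helix: two consecutive n-turns at i-1 and i -> residues i..i+k-1
    for k, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                for j in range(i, i + k):
                    claim(j, code)

    # strands: bridges with an adjacent bridge residue extend to ladders (E);
    # isolated bridges are B
    bridged = para | anti
    for i in range(n):
        if not bridged[i]:
            continue
        neighbour = (i > 0 and bridged[i - 1]) or (i + 1 < n and bridged[i + 1])
        claim(i, "E" if neighbour else "B")

    # turns: residues spanned by any n-turn
    for k in (3, 4, 5):
        for i in range(n):
            if turn[k][i]:
                for j in range(i + 1, min(i + k, n)):
                    claim(j, "T")

    # bends: CA(i-2), CA(i), CA(i+2) kappa angle > 70 deg
    for i in range(2, n - 2):
        if not contiguous(i - 2, i + 2):
            continue
        u = bb[i].ca - bb[i - 2].ca
        v = bb[i + 2].ca - bb[i].ca
        cu, cv = np.linalg.norm(u), np.linalg.norm(v)
        if cu == 0 or cv == 0:
            continue
        kappa = np.degrees(np.arccos(np.clip(np.dot(u, v) / (cu * cv), -1, 1)))
        if kappa > 70.0:
            claim(i, "S")

    return SecondaryStructure(residue_keys=[r.key for r in bb], ss8=ss8)

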