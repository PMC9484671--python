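"""Empirical amine pKa estimation with a pluggable backend contract.

The built-in backend is a deliberately simple conformation-based
heuristic in the spirit of fast empirical predictors: a model pKa for
the free amine (10.5 for the lysine ε-amino group, 8.0 for an α-amino
terminus) plus two additive structural shifts,

* desolvation: +0.01 per heavy atom within 9 Å of the amine nitrogen
  beyond a 280-atom baseline (buried amines titrate higher), and
* charge-charge: for every charged group within 7 Å, a linear
  distance-damped shift of ±0.5 * (1 - d/7) — anions (Asp/Glu
  carboxylate oxygens, C-terminal carboxylate) raise the pKa,
  cations (Arg CZ, other Lys NZ, N-terminal N) lower it.

The terms are reported per site, so pka == model + desolvation +
charge holds exactly.  The heuristic's only role downstream is the
pKa <= 10.3 branch of the decision tree; it is not a replacement for a
full empirical predictor, and a PROPKA-compatible program can be
plugged in as the "external" backend where installed.

pH does not enter the pKa value itself; the virtual pH in RunConfig is
protocol metadata for interpreting results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .config import RunConfig
from .errors import ConfigurationError, LookupFailure
from .structure_io import AmineSite, StructureModel

logger = logging.getLogger(__name__)

#: atoms taken as centres of charged groups: name -> (residue filter, sign)
_ANION_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_CATION_ATOMS = {("ARG", "CZ"), ("LYS", "NZ")}


@dataclass
class PkaResult:
    """Predicted pKa of one amine, with its additive term breakdown."""

    site: AmineSite
    pka: float
    model_value: float
    desolvation_shift: float
    hbond_shift: float  # reserved term; the built-in heuristic sets 0
    charge_shift: float
    backend: str = "builtin"

    def __post_init__(self) -> None:
        if not (0.0 < self.pka < 16.0):
            raise ValueError(f"pKa {self.pka:.2f} out of physical range for "
                             f"{self.site.site_id}")


def predict_pka(model: StructureModel, site: AmineSite,
                config: RunConfig | None = None) -> PkaResult:
    """Built-in heuristic pKa for one amine site."""
    cfg = config or RunConfig()
    n_atom = site.nitrogen
    if n_atom is None:
        raise LookupFailure(f"site {site.site_id}: amine nitrogen missing")
    n_pos = n_atom.coordinates

    base = cfg.pka_model_epsilon if site.amine_kind == "epsilon" else cfg.pka_model_alpha

    heavies = [a for a in model.atoms if a.element not in ("H", "D")]
    pos = np.array([a.coordinates for a in heavies])
    d = np.linalg.norm(pos - n_pos, axis=1)
    buried = int(np.sum(d <= cfg.pka_burial_cutoff)) - 1  # exclude the N itself
    desolv = cfg.pka_burial_coeff * max(0, buried - cfg.pka_burial_baseline)

    charge = 0.0
    residues = model.residues()
    first_last = _chain_termini(residues)
    for a, dist in zip(heavies, d):
        # own-residue groups are part of the site, not its environment
        if dist > cfg.pka_charge_cutoff or a.residue_key == site.residue_key:
            continue
        sign = 0
        key = (a.residue_name, a.name)
        if key in _ANION_ATOMS or a.name == "OXT":
            sign = +1
        elif key in _CATION_ATOMS:
            sign = -1
        elif a.name == "N" and a.residue_key in first_last:
            sign = -1  # protonated N-terminal amine
        if sign:
            charge += sign * cfg.pka_charge_coeff * (1.0 - dist / cfg.pka_charge_cutoff)

    return PkaResult(site=site, pka=base + desolv + charge, model_value=base,
                     desolvation_shift=desolv, hbond_shift=0.0,
                     charge_shift=charge, backend="builtin")


def _chain_termini(residues) -> set:
    """Keys of each chain's first standard residue (N-terminal amines)."""
    seen: dict[str, tuple] = {}
    for r in residues:
        if r.is_standard and r.chain_id not in seen:
            seen[r.chain_id] = r.key
    return set(seen.values())


PkaBackend = Callable[[StructureModel, AmineSite, RunConfig], PkaResult]


def _external_backend(model: StructureModel, site: AmineSite,
                      config: RunConfig) -> PkaResult:
    """PROPKA-compatible external predictor (optional dependency)."""
    try:
        import propka.run  # noqa: F401
    except ImportError as e:
        raise ConfigurationError(
            "external pKa backend requested but the 'propka' package is not "
            "installed; install the [propka] extra or use backend 'builtin'"
        ) from e
    from . import structure_io
    import tempfile
    import os

    with tempfile.TemporaryDirectory() as tmp:
        pdb_path = os.path.join(tmp, "model.pdb")
        structure_io.write_pdb(model, pdb_path)
        mol = propka.run.single(pdb_path, write_pka=False)
        group_name = "NZ" if site.amine_kind == "epsilon" else "N+"
        for group in mol.conformations["AVR"].groups:
            atom = group.atom
            if (group.type in ("LYS", "N+")
                    and atom.res_num == site.residue_number
                    and (atom.chain_id or "A") == site.chain_id
                    and ((site.amine_kind == "epsilon" and group.type == "LYS")
                         or (site.amine_kind == "alpha" and group.type == "N+"))):
                pka = float(group.pka_value)
                model_v = float(group.model_pka)
                return PkaResult(site=site, pka=pka, model_value=model_v,
                                 desolvation_shift=pka - model_v, hbond_shift=0.0,
                                 charge_shift=0.0, backend="external")
    raise LookupFailure(f"external backend returned no pKa for {site.site_id}")


def get_pka_backend(name: str) -> PkaBackend:
    """Resolve a backend by name; any backend maps (model, site, config) -> PkaResult."""
    if name == "builtin":
        return predict_pka
    if name == "external":
        # fail fast if the optional dependency is absent
        try:
            import propka.run  # noqa: F401
        except ImportError as e:
            raise ConfigurationError(
                "external pKa backend unavailable: propka is not installed") from e
        return _external_backend
    raise ConfigurationError(f"unknown pKa backend {name!r} (expected builtin|external)")
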