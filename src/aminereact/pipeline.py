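"""Orchestration: one scoring run, probe-radius scans, table output.

A run executes clean → (optional) assembly selection → hydrogen
placement → SASA → pKa → secondary structure → H-bonds →
electrostatics → classification and emits one row per amine site.
Everything is recomputed on the selected chain subset — nothing is
cached across subsets — and a run is fully deterministic for fixed
inputs and configuration.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classifier import DEFAULT_RULES, classify_site, load_rules
from .config import RunConfig
from .electrostatics import site_charge_flag
from .errors import AmineReactError, ConfigurationError, LookupFailure, ReconciliationError
from .hbond import detect_hbonds, is_amine_donor
from .pka import get_pka_backend
from .sasa import SasaParams, compute_atom_sasa, residue_esa_table
from .secondary_structure import assign_ss
from .structure_io import (ChargedAtom, StructureModel, clean_structure,
                           enumerate_amine_sites, parse_pdb, parse_pqr,
                           place_missing_hydrogens, select_assembly)
from .classifier import SiteParameters

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["site_id", "residue_name", "amine_kind", "esa", "pka", "ss8",
                 "ss3", "h_donor", "coulomb_energy", "low_positive_charge",
                 "reactivity_class", "rule_path"]


def run(pdb: str | Path, pqr: str | Path, config: Optional[RunConfig] = None
        ) -> pd.DataFrame:
    """Score every amine site of a PDB/PQR input pair.

    Returns the site table: one row per α-/ε-amino site with the five
    computed parameters and the decision-tree class.
    """
    cfg = config or RunConfig()
    cfg.validate()
    model = parse_pdb(pdb)
    charged = parse_pqr(pqr)
    pqr_chainless = _looks_chainless(charged, model)
    return run_model(model, charged, cfg, pqr_chainless=pqr_chainless)


def _looks_chainless(charged: Sequence[ChargedAtom], model: StructureModel) -> bool:
    pqr_chains = {a.chain_id for a in charged}
    return pqr_chains == {"A"} and set(model.chains) != {"A"}


def run_model(model: StructureModel, charged: Sequence[ChargedAtom],
              config: Optional[RunConfig] = None,
              pqr_chainless: bool = False) -> pd.DataFrame:
    """Score an in-memory model against an in-memory charge list."""
    cfg = config or RunConfig()
    cfg.validate()
    t0 = time.perf_counter()

    def stage(name: str) -> None:
        logger.info("stage %-18s %7.3f s", name, time.perf_counter() - t0)

    model = clean_structure(model, keep_hetero=cfg.keep_hetero)
    stage("clean")
    if cfg.chains is not None:
        if not list(cfg.chains):
            raise ConfigurationError("empty chain selection")
        model = select_assembly(model, cfg.chains)
        if pqr_chainless:
            if len(list(cfg.chains)) != 1:
                raise ReconciliationError(
                    "chain-less PQR cannot be reconciled with a multi-chain selection")
        else:
            charged = [a for a in charged if a.chain_id in set(cfg.chains)]
        stage("select_assembly")
    sites = enumerate_amine_sites(model)
    if not sites:
        raise AmineReactError("no amine sites to score")
    # reconcile site nitrogens against the PQR before any computation
    from .electrostatics import find_site_nitrogen
    unmatched = []
    for s in sites:
        try:
            find_site_nitrogen(charged, s, chainless=pqr_chainless)
        except LookupFailure:
            unmatched.append(s.site_id)
    if unmatched:
        raise ReconciliationError(
            f"PQR does not contain the site nitrogen(s) for: {', '.join(unmatched)}")
    stage("reconcile")

    protonated = place_missing_hydrogens(model)
    stage("protonate")

    params = SasaParams(probe_radius=cfg.probe_radius,
                        algorithm=cfg.sasa_algorithm,
                        resolution=cfg.sasa_resolution)
    areas = compute_atom_sasa(protonated, params)
    esa_by_res = residue_esa_table(areas)
    stage("sasa")

    backend = get_pka_backend(cfg.pka_backend)
    pkas = {s.site_id: backend(model, s, cfg) for s in sites}
    stage("pka")

    ss = assign_ss(model)
    stage("secondary_structure")

    bonds = detect_hbonds(protonated, cfg.hbond_distance, cfg.hbond_angle)
    stage("hbond")

    elec = {s.site_id: site_charge_flag(charged, s, cfg, chainless=pqr_chainless)
            for s in sites}
    stage("electrostatics")

    rules = load_rules(cfg.classifier_rules) if cfg.classifier_rules else DEFAULT_RULES
    rows = []
    for s in sites:
        p = SiteParameters(
            site=s,
            esa=esa_by_res.get(s.residue_key, 0.0),
            pka=pkas[s.site_id].pka,
            ss3=ss.ss3_of(s.residue_key),
            h_donor=is_amine_donor(s, bonds),
            coulomb_energy=elec[s.site_id].energy,
            low_positive_charge=elec[s.site_id].low_positive_charge,
        )
        cls = classify_site(p, cfg.thresholds, rules)
        rows.append({
            "site_id": s.site_id,
            "residue_name": s.residue_name,
            "amine_kind": s.amine_kind,
            "esa": p.esa,
            "pka": p.pka,
            "ss8": ss.ss8_of(s.residue_key),
            "ss3": p.ss3,
            "h_donor": p.h_donor,
            "coulomb_energy": p.coulomb_energy,
            "low_positive_charge": p.low_positive_charge,
            "reactivity_class": cls.label,
            "rule_path": ";".join(cls.rule_path),
        })
    stage("classify")
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def scan_probe_radii(pdb: str | Path, pqr: str | Path, radii: Sequence[float],
                     config: Optional[RunConfig] = None
                     ) -> tuple[dict[float, pd.DataFrame], pd.DataFrame]:
    """One full run per probe radius, plus the classification flip report.

    The flip report lists every site whose class changes between
    consecutive radii (in the given order).
    """
    radii = list(radii)
    if len(set(radii)) != len(radii) or any(r <= 0 for r in radii):
        raise ConfigurationError("probe radii must be positive and distinct")
    cfg = config or RunConfig()
    model = parse_pdb(pdb)
    charged = parse_pqr(pqr)
    chainless = _looks_chainless(charged, model)
    tables: dict[float, pd.DataFrame] = {}
    for r in radii:
        try:
            tables[r] = run_model(model, charged, cfg.with_probe_radius(r),
                                  pqr_chainless=chainless)
        except AmineReactError as e:
            raise AmineReactError(f"probe radius {r}: {e}") from e
    flips = []
    for r_prev, r_next in zip(radii, radii[1:]):
        a = tables[r_prev].set_index("site_id")["reactivity_class"]
        b = tables[r_next].set_index("site_id")["reactivity_class"]
        for site_id in a.index:
            if a[site_id] != b[site_id]:
                flips.append({"site_id": site_id, "radius_from": r_prev,
                              "radius_to": r_next, "class_from": a[site_id],
                              "class_to": b[site_id]})
    return tables, pd.DataFrame(flips, columns=["site_id", "radius_from",
                                                "radius_to", "class_from",
                                                "class_to"])


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the report CSV (2-decimal floats) plus a machine-precision
    long-format CSV alongside (suffix ``.long.csv``).

    Returns the long-format path.  Reruns on identical inputs produce
    byte-identical files.
    """
    if table.empty:
        raise AmineReactError("refusing to write an empty site table")
    path = Path(path)
    rounded = table.copy()
    for col in ("esa", "pka", "coulomb_energy"):
        rounded[col] = rounded[col].map(lambda v: f"{v:.2f}")
    rounded.to_csv(path, index=False, lineterminator="\n")
    long_path = path.with_suffix(".long.csv")
    table.to_csv(long_path, index=False, float_format="%.17g", lineterminator="\n")
    return long_path


def read_long_table(path: str | Path) -> pd.DataFrame:
    """Read back a long-format table (bit-exact float round-trip)."""
    return pd.read_csv(path, dtype={c: t for c, t in zip(
        TABLE_COLUMNS, [str, str, str, float, float, str, str, bool, float,
                        bool, str, str])})
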