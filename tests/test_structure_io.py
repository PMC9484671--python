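"""Parsing, cleaning, assembly selection, site enumeration, protonation."""

import numpy as np
import pytest

from aminereact import fixtures as fx
from aminereact.errors import EmptyStructureError, LookupFailure, ParseError
from aminereact.structure_io import (AtomRecord, StructureModel, clean_structure,
                                     enumerate_amine_sites, parse_pdb, parse_pqr,
                                     place_missing_hydrogens, select_assembly,
                                     write_pdb, write_pqr)


class TestPdbRoundTrip:
    def test_write_then_parse_preserves_structure(self, helix12, tmp_path):
        p = tmp_path / "helix.pdb"
        write_pdb(helix12, p)
        back = parse_pdb(p)
        assert len(back.atoms) == len(helix12.atoms)
        assert [a.name for a in back.atoms] == [a.name for a in helix12.atoms]
        assert back.chains == helix12.chains
        # PDB fixed format carries 3 decimals
        assert np.abs(back.coordinates() - helix12.coordinates()).max() < 1.5e-3

    def test_residue_numbers_kept_verbatim(self, tmp_path):
        m = fx.build_peptide("AKA", start_number=41)
        p = tmp_path / "m.pdb"
        write_pdb(m, p)
        back = parse_pdb(p)
        assert sorted({a.residue_number for a in back.atoms}) == [41, 42, 43]

    def test_missing_file_is_parse_error(self, tmp_path):
        with pytest.raises(ParseError):
            parse_pdb(tmp_path / "nope.pdb")

    def test_three_residue_fixture(self, tmp_path):
        m = fx.build_peptide("AAA")
        p = tmp_path / "aaa.pdb"
        write_pdb(m, p)
        back = parse_pdb(p)
        assert len(back.residues()) == 3
        assert back.chains == ["A"]


class TestPqr:
    def test_direct_field_mapping(self, tmp_path):
        p = tmp_path / "one.pqr"
        p.write_text("ATOM 1 N LYS A 1 0.0 0.0 0.0 -0.3000 1.8240\n")
        atoms = parse_pqr(p)
        assert len(atoms) == 1
        a = atoms[0]
        assert a.partial_charge == pytest.approx(-0.30)
        assert a.radius == pytest.approx(1.824)
        assert a.chain_id == "A"

    def test_chainless_dialect_assigns_chain_a(self, tmp_path):
        p = tmp_path / "nochain.pqr"
        p.write_text("ATOM 1 N LYS 1 0.0 0.0 0.0 -0.3 1.8\n"
                     "ATOM 2 CA LYS 1 1.5 0.0 0.0 0.1 1.9\n")
        atoms = parse_pqr(p)
        assert {a.chain_id for a in atoms} == {"A"}

    def test_charge_conservation(self, tmp_path):
        p = tmp_path / "two.pqr"
        p.write_text("ATOM 1 Q CHG A 1 0 0 0 1.0 1.5\n"
                     "ATOM 2 Q CHG A 2 4 0 0 1.0 1.5\n")
        atoms = parse_pqr(p)
        assert sum(a.partial_charge for a in atoms) == pytest.approx(2.0)

    def test_non_numeric_charge_names_line(self, tmp_path):
        p = tmp_path / "bad.pqr"
        p.write_text("ATOM 1 N LYS A 1 0.0 0.0 0.0 oops 1.8\n")
        with pytest.raises(ParseError, match=":1"):
            parse_pqr(p)

    def test_write_parse_round_trip(self, helix12):
        charged = fx.model_to_pqr(helix12)
        import io, tempfile, os
        import pathlib
        with tempfile.TemporaryDirectory() as d:
            path = pathlib.Path(d) / "h.pqr"
            write_pqr(charged, path)
            back = parse_pqr(path)
        assert len(back) == len(charged)
        assert sum(a.partial_charge for a in back) == pytest.approx(
            sum(a.partial_charge for a in charged))


class TestClean:
    def test_waters_always_removed(self, helix12):
        wet = StructureModel(helix12.atoms + [
            AtomRecord(999, "O", "O", "HOH", "A", 900, np.zeros(3), is_hetero=True)])
        cleaned = clean_structure(wet, keep_hetero=True)
        assert not any(a.residue_name == "HOH" for a in cleaned.atoms)

    def test_idempotent_without_waters(self, helix12):
        assert len(clean_structure(helix12).atoms) == len(helix12.atoms)

    def test_hetero_removed_unless_kept(self, helix12):
        het = StructureModel(helix12.atoms + [
            AtomRecord(998, "FE", "FE", "HEM", "A", 901, np.ones(3), is_hetero=True)])
        assert not any(a.is_hetero for a in clean_structure(het).atoms)
        assert any(a.is_hetero for a in clean_structure(het, keep_hetero=True).atoms)

    def test_only_waters_is_empty_structure(self):
        wet = StructureModel([
            AtomRecord(1, "O", "O", "HOH", "A", 1, np.zeros(3), is_hetero=True)])
        with pytest.raises(EmptyStructureError):
            clean_structure(wet)


class TestSelectAssembly:
    def test_identity_when_all_chains(self, helix12):
        sub = select_assembly(helix12, helix12.chains)
        assert len(sub.atoms) == len(helix12.atoms)

    def test_symmetric_homodimer_halves(self, helix12):
        dimer = fx.build_homodimer(helix12, [50.0, 0.0, 0.0])
        sub = select_assembly(dimer, ["A"])
        assert len(sub.atoms) * 2 == len(dimer.atoms)

    def test_unknown_chain_lists_available(self, helix12):
        with pytest.raises(LookupFailure, match="available"):
            select_assembly(helix12, ["Z"])

    def test_select_then_enumerate_commutes(self, helix12):
        dimer = fx.build_homodimer(helix12, [50.0, 0.0, 0.0])
        direct = [s.site_id for s in enumerate_amine_sites(select_assembly(dimer, ["B"]))]
        filtered = [s.site_id for s in enumerate_amine_sites(dimer)
                    if s.chain_id == "B"]
        assert direct == filtered


class TestEnumerateSites:
    def test_helix_with_one_lysine(self, helix12):
        sites = enumerate_amine_sites(helix12)
        assert [s.site_id for s in sites] == ["A:1:alpha", "A:6:epsilon"]
        assert sites[0].nitrogen.name == "N"
        assert sites[1].nitrogen.name == "NZ"

    def test_n_terminal_lysine_yields_both_kinds(self, lysine_alone):
        sites = enumerate_amine_sites(lysine_alone)
        assert [s.amine_kind for s in sites] == ["alpha", "epsilon"]
        assert {s.residue_number for s in sites} == {1}

    def test_invariant_under_atom_permutation_within_residues(self, helix12, rng):
        atoms = []
        for res in helix12.residues():
            group = list(res.atoms)
            atoms.extend(group[i] for i in rng.permutation(len(group)))
        shuffled = StructureModel(atoms)
        assert ([s.site_id for s in enumerate_amine_sites(shuffled)]
                == [s.site_id for s in enumerate_amine_sites(helix12)])

    def test_dimer_doubles_sites(self, helix12):
        dimer = fx.build_homodimer(helix12, [50.0, 0.0, 0.0])
        assert len(enumerate_amine_sites(dimer)) == 2 * len(enumerate_amine_sites(helix12))


class TestHydrogenPlacement:
    def test_amide_h_bond_length(self, helix12_protonated):
        for res in helix12_protonated.residues()[1:]:
            h = res.atom("H")
            assert h is not None
            d = np.linalg.norm(h.coordinates - res.atom("N").coordinates)
            assert d == pytest.approx(1.01, abs=1e-3)

    def test_lysine_nz_gets_three_tetrahedral_h(self, helix12_protonated):
        lys = helix12_protonated.residue("A", 6)
        hzs = [a for a in lys.atoms if a.name.startswith("HZ")]
        assert len(hzs) == 3
        nz = lys.atom("NZ").coordinates
        for h in hzs:
            assert np.linalg.norm(h.coordinates - nz) == pytest.approx(1.01, abs=1e-3)

    def test_idempotent_on_protonated_model(self, helix12_protonated):
        again = place_missing_hydrogens(helix12_protonated)
        assert len(again.atoms) == len(helix12_protonated.atoms)

    def test_first_residue_has_no_amide_h(self, helix12_protonated):
        assert helix12_protonated.residues()[0].atom("H") is None

    def test_proline_gets_no_amide_h(self):
        m = fx.build_peptide("APA")
        prot = place_missing_hydrogens(m)
        pro = prot.residue("A", 2)
        assert pro.name == "PRO"
        assert pro.atom("H") is None
        # the following alanine still gets one
        assert prot.residue("A", 3).atom("H") is not None
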