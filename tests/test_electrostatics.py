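"""Coulomb energy: closed forms, brute-force equality, invariances."""

import numpy as np
import pytest

from aminereact import fixtures as fx
from aminereact.config import RunConfig
from aminereact.electrostatics import (COULOMB_K, atom_coulomb_energy,
                                       site_charge_flag)
from aminereact.errors import LookupFailure
from aminereact.structure_io import AmineSite, AtomRecord, ChargedAtom


def brute_force_energy(charged, target, dielectric=1.0, exclude_same_residue=True):
    """Literal O(n^2)-style double-loop Coulomb sum (the oracle)."""
    e = 0.0
    for a in charged:
        if a is target:
            continue
        if exclude_same_residue and a.residue_key == target.residue_key:
            continue
        r = float(np.linalg.norm(a.coordinates - target.coordinates))
        if r < 0.5:
            continue
        e += COULOMB_K * target.partial_charge * a.partial_charge / (dielectric * r)
    return e


class TestClosedForms:
    def test_calibration_pair_is_100(self):
        pair = fx.build_calibration_pair()
        assert atom_coulomb_energy(pair, pair[0]) == pytest.approx(100.0, abs=1e-9)

    def test_single_atom_zero(self):
        solo = fx.build_charge_system([[0, 0, 0]], [2.0])
        assert atom_coulomb_energy(solo, solo[0]) == 0.0

    def test_doubling_dielectric_halves_energy(self):
        pair = fx.build_calibration_pair()
        e1 = atom_coulomb_energy(pair, pair[0], dielectric=1.0)
        e2 = atom_coulomb_energy(pair, pair[0], dielectric=2.0)
        assert e2 == pytest.approx(e1 / 2.0)

    def test_symmetric_layout_cancels(self):
        sym = fx.build_symmetric_cancellation()
        assert atom_coulomb_energy(sym, sym[0]) == pytest.approx(0.0, abs=1e-10)

    def test_missing_target_is_lookup_error(self):
        pair = fx.build_calibration_pair()
        stranger = fx.build_charge_system([[9, 9, 9]], [1.0])[0]
        with pytest.raises(LookupFailure):
            atom_coulomb_energy(pair, stranger)


class TestBruteForceOracle:
    def test_exact_equality_on_random_system(self, rng):
        pos = rng.uniform(-10, 10, size=(60, 3))
        q = rng.uniform(-1, 1, size=60)
        charged = fx.build_charge_system(pos, q)
        for target in charged[:10]:
            assert atom_coulomb_energy(charged, target) == pytest.approx(
                brute_force_energy(charged, target), rel=1e-12)

    def test_same_residue_exclusion_matches_oracle(self, helix12):
        charged = fx.model_to_pqr(helix12)
        nz = next(a for a in charged if a.name == "NZ")
        assert atom_coulomb_energy(charged, nz) == pytest.approx(
            brute_force_energy(charged, nz), rel=1e-12)
        # and switching exclusion off also matches
        assert atom_coulomb_energy(charged, nz, exclude_same_residue=False) == \
            pytest.approx(brute_force_energy(charged, nz,
                                             exclude_same_residue=False), rel=1e-12)


class TestInvariances:
    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        pos = rng.uniform(-5, 5, size=(20, 3))
        q = rng.uniform(-1, 1, size=20)
        charged = fx.build_charge_system(pos, q)
        base = atom_coulomb_energy(charged, charged[0])
        rot = Rotation.from_rotvec([0.5, 0.5, -0.3]).as_matrix()
        moved = fx.build_charge_system(pos @ rot.T + np.array([3.0, 4, 5]), q)
        assert atom_coulomb_energy(moved, moved[0]) == pytest.approx(base, rel=1e-10)

    def test_atom_order_invariance(self, rng):
        pos = rng.uniform(-5, 5, size=(15, 3))
        q = rng.uniform(-1, 1, size=15)
        charged = fx.build_charge_system(pos, q)
        order = rng.permutation(15)
        shuffled = [charged[i] for i in order]
        assert atom_coulomb_energy(shuffled, charged[4]) == pytest.approx(
            atom_coulomb_energy(charged, charged[4]), rel=1e-12)

    def test_charge_scaling_is_quadratic(self):
        pair = fx.build_calibration_pair()
        lam = 1.7
        scaled = fx.build_charge_system(
            [a.coordinates for a in pair],
            [a.partial_charge * lam for a in pair])
        assert atom_coulomb_energy(scaled, scaled[0]) == pytest.approx(
            lam * lam * atom_coulomb_energy(pair, pair[0]))


def _lys_site_and_charges(energy_target, distance=None):
    """A LYS NZ plus one unit charge placed to yield a chosen energy."""
    d = distance if distance is not None else COULOMB_K / energy_target
    nz_rec = AtomRecord(1, "NZ", "N", "LYS", "A", 1, np.zeros(3))
    charged = [
        ChargedAtom(1, "NZ", "N", "LYS", "A", 1, np.zeros(3),
                    partial_charge=1.0, radius=1.8),
        ChargedAtom(2, "Q", "X", "CHG", "A", 2, np.array([d, 0.0, 0.0]),
                    partial_charge=1.0, radius=1.5),
    ]
    site = AmineSite("A:1:epsilon", "A", 1, "", "LYS", "epsilon", nz_rec)
    return site, charged


class TestChargeFlag:
    def test_exactly_100_is_not_flagged(self):
        # the calibration distance gives E = 100.0 to within one ulp below
        site, charged = _lys_site_and_charges(100.0,
                                              distance=fx.CALIBRATION_DISTANCE)
        r = site_charge_flag(charged, site, RunConfig())
        assert r.energy == pytest.approx(100.0, abs=1e-9)
        assert r.low_positive_charge is False

    def test_just_above_100_is_flagged(self):
        site, charged = _lys_site_and_charges(100.01)
        r = site_charge_flag(charged, site, RunConfig())
        assert r.low_positive_charge is True

    def test_symmetric_environment_not_flagged(self):
        sym = fx.build_symmetric_cancellation()
        nz = ChargedAtom(10, "NZ", "N", "LYS", "A", 10, np.zeros(3),
                         partial_charge=1.0, radius=1.8)
        charged = [nz] + [a for a in sym[1:]]
        site = AmineSite("A:10:epsilon", "A", 10, "", "LYS", "epsilon",
                         AtomRecord(10, "NZ", "N", "LYS", "A", 10, np.zeros(3)))
        r = site_charge_flag(charged, site, RunConfig())
        assert r.energy == pytest.approx(0.0, abs=1e-10)
        assert r.low_positive_charge is False

    def test_missing_nz_names_site(self):
        site, charged = _lys_site_and_charges(100.0)
        with pytest.raises(LookupFailure, match="A:1:epsilon"):
            site_charge_flag(charged[1:], site, RunConfig())
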