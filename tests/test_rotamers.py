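"""Torsion grid search: enumeration, clash filtering, winner selection."""

import numpy as np
import pytest

from chpi import (
    RotatableBond,
    best_rotamer,
    build_monomer,
    clash_filter,
    enumerate_rotamers,
    total_energy,
)
from chpi.rotamers import NoValidRotamerError
from chpi.scoring import ChPiParamsH
from conftest import make_structure

TET = 109.4712206


def rotor_ligand(with_oxygen=False, height=4.2):
    """C1-C2 rotor over the origin: C2 carries one H pointing straight down
    (and optionally an O pointing straight up) at torsion angle 0."""
    c2 = np.array([0.0, 0.0, height])
    c1 = c2 + np.array([1.54, 0.0, 0.0])

    def substituent(beta_deg, length):
        b = np.deg2rad(beta_deg)
        d = np.array([np.cos(np.deg2rad(TET)),
                      np.sin(np.deg2rad(TET)) * np.cos(b),
                      np.sin(np.deg2rad(TET)) * np.sin(b)])
        return c2 + length * d

    recs = [("C1", "C", c1), ("C2", "C", c2), ("H1", "H", substituent(-90.0, 1.09))]
    bonds = [(0, 1), (1, 2)]
    if with_oxygen:
        recs.append(("O1", "O", substituent(90.0, 1.43)))
        bonds.append((1, 3))
    return make_structure(recs, bonds=bonds)


def receptor_ring(with_donors=False, height=4.2):
    """Benzene ring in the xy plane; optionally a cluster of three N-H
    donors posed to hydrogen-bond the rotor oxygen of :func:`rotor_ligand`
    when it swings toward +y."""
    recs = []
    for k in range(6):
        a = np.deg2rad(60 * k)
        recs.append((f"C{k+1}", "C", (1.391 * np.cos(a), 1.391 * np.sin(a), 0.0),
                     {"residue_name": "PHE"}))
    if with_donors:
        o_target = np.array([-0.477, 1.348, height])
        for k, d in enumerate([np.array([0.0, 1.0, 0.0]),
                               np.array([0.766, 0.643, 0.0]),
                               np.array([-0.766, 0.643, 0.0])]):
            n = o_target + 3.3 * d
            recs.append((f"N{k+1}", "N", tuple(n), {"residue_name": "ASN"}))
            recs.append((f"HN{k+1}", "H", tuple(n + np.array([0.0, 0.9, 0.0])),
                         {"residue_name": "ASN"}))
    return make_structure(recs)


BOND = RotatableBond(axis_atoms=(0, 1), moving_set=(2,))


class TestEnumeration:
    def test_counts_120_per_bond(self):
        lig = rotor_ligand()
        assert sum(1 for _ in enumerate_rotamers(lig, [BOND])) == 120

    def test_counts_squared_for_two_bonds(self):
        lig = rotor_ligand(with_oxygen=True)
        b2 = RotatableBond(axis_atoms=(1, 3), moving_set=(2,), kind="side-chain chi2")
        n = sum(1 for _ in enumerate_rotamers(lig, [BOND, b2]))
        assert n == 120 ** 2 == 14400

    def test_zero_angle_conformation_identical(self):
        lig = rotor_ligand()
        angles, conf = next(iter(enumerate_rotamers(lig, [BOND])))
        assert angles == (0.0,)
        assert np.allclose(conf.coords, lig.coords)

    def test_invalid_bond_counts(self):
        lig = rotor_ligand()
        with pytest.raises(ValueError):
            list(enumerate_rotamers(lig, []))
        with pytest.raises(ValueError):
            list(enumerate_rotamers(lig, [BOND, BOND, BOND]))

    def test_rotation_preserves_internal_geometry(self):
        lig = rotor_ligand(with_oxygen=True)
        bond = RotatableBond(axis_atoms=(0, 1), moving_set=(2, 3))
        ref = lig.coords
        for angles, conf in enumerate_rotamers(lig, [bond], step=45.0):
            x = conf.coords
            for i in (2, 3):
                for j in (0, 1, 2, 3):
                    assert np.isclose(
                        np.linalg.norm(x[i] - x[j]), np.linalg.norm(ref[i] - ref[j]),
                        atol=1e-6,
                    )


class TestClashFilter:
    def chain(self, *atoms):
        recs, bonds = [], []
        for k, (el, xyz) in enumerate(atoms):
            recs.append((f"{el}{k}", el, xyz))
            if k:
                bonds.append((k - 1, k))
        return make_structure(recs, bonds=bonds, typed=False)

    def test_heavy_heavy_at_1_9_rejected(self):
        s = self.chain(("C", (0, 0, 0)), ("C", (1.5, 0, 0)), ("C", (2.2, 1.2, 0)),
                       ("C", (1.9, 0, 0)))
        assert clash_filter(s) is True

    def test_heavy_hydrogen_at_1_8_kept(self):
        s = self.chain(("C", (0, 0, 0)), ("C", (1.5, 0, 0)), ("C", (2.2, 1.2, 0)),
                       ("H", (1.8, 0, 0)))
        assert clash_filter(s) is False

    def test_hydrogen_hydrogen_at_1_40_rejected_inclusive(self):
        s = self.chain(("H", (0, 0, 0)), ("C", (1.0, 0, 0)), ("C", (1.8, 1.2, 0)),
                       ("H", (1.4, 0, 0)))
        assert clash_filter(s) is True

    def test_bonded_pairs_exempt(self):
        s = self.chain(("C", (0, 0, 0)), ("C", (1.5, 0, 0)), ("C", (2.2, 1.2, 0)))
        assert clash_filter(s) is False  # 1-2 and 1-3 only


class TestBestRotamer:
    def test_reference_pose_recovered_when_it_is_the_minimum(self):
        rec = receptor_ring()
        lig = rotor_ligand()
        res = best_rotamer(rec, lig, [BOND], w=0.7, mode="hdep")
        assert res.best_angles == (0.0,)
        assert res.angle_deviation == (0.0,)
        assert res.rmsd_to_reference == 0.0
        assert res.n_enumerated == 120

    def test_winner_is_exhaustive_minimum(self):
        rec = receptor_ring()
        lig = rotor_ligand()
        res = best_rotamer(rec, lig, [BOND], w=0.7, mode="hdep")
        totals = []
        for _, conf in enumerate_rotamers(lig, [BOND]):
            if not clash_filter(conf):
                totals.append(total_energy(rec, conf, w=0.7, mode="hdep").total)
        assert res.best_breakdown.total <= min(totals) + 1e-12

    def test_weighting_flips_hbond_decoy_to_chpi_pose(self):
        """Without the CH-pi term the rotor prefers a hydrogen bond to the
        nearby donor; at w = 0.7 the CH-pi pose wins."""
        rec = receptor_ring(with_donors=True, height=4.6)
        lig = rotor_ligand(with_oxygen=True, height=4.6)
        bond = RotatableBond(axis_atoms=(0, 1), moving_set=(2, 3))
        res0 = best_rotamer(rec, lig, [bond], w=0.0, mode="hdep")
        res7 = best_rotamer(rec, lig, [bond], w=0.7, mode="hdep")
        # decoy: O swung toward the donor cluster, no CH-pi contact
        assert 60.0 <= res0.best_angles[0] <= 120.0
        assert res0.best_breakdown.e_chpi == 0.0
        # CH-pi pose: hydrogen back over the ring face (angle near 0)
        assert res7.best_angles[0] <= 30.0 or res7.best_angles[0] >= 330.0
        assert res7.best_breakdown.e_chpi < -0.5

    def test_w0_independent_of_chpi_parameters(self):
        rec = receptor_ring()
        lig = rotor_ligand()
        r1 = best_rotamer(rec, lig, [BOND], w=0.0, mode="hdep")
        weird = ChPiParamsH(e=0.49, r0=2.0, c=1.9)
        totals = [total_energy(rec, conf, w=0.0, mode="hdep", params=weird).total
                  for _, conf in enumerate_rotamers(lig, [BOND])]
        assert np.isclose(r1.best_breakdown.total, min(totals), atol=1e-12)

    def test_tie_breaks_to_first_angle(self):
        rec = receptor_ring()
        far = rotor_ligand()
        for a in far.atoms:
            a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        res = best_rotamer(rec, far, [BOND], w=0.7)
        assert res.best_angles == (0.0,)
        assert res.best_breakdown.total == 0.0

    def test_all_clashing_raises(self):
        c2 = np.array([0.0, 0.0, 4.2])
        c1 = c2 + np.array([1.54, 0.0, 0.0])
        h = c2 + 1.09 * np.array([np.cos(np.deg2rad(TET)),
                                  np.sin(np.deg2rad(TET)), 0.0])
        blocker = c2 + 1.09 * np.array([np.cos(np.deg2rad(TET)), 0.0, 0.0])
        lig = make_structure(
            [("C1", "C", c1), ("C2", "C", c2), ("H1", "H", h), ("C3", "C", blocker)],
            bonds=[(0, 1), (1, 2), (0, 3)],
        )
        with pytest.raises(NoValidRotamerError):
            best_rotamer(receptor_ring(), lig, [BOND], w=0.7)
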