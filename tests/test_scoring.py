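"""Base score, CH-pi energy forms, and their combination."""

import math

import numpy as np
import pytest

from chpi import (
    DimerSpec,
    assign_atom_types,
    build_dimer,
    e_chpi_c,
    e_chpi_h,
    f_theta,
    perceive_aromatic_rings,
    total_energy,
    vina_base_energy,
)
from chpi.rings import AromaticRing
from chpi.scoring import BASE_PARAMS, PAIR_SCALE, ChPiParamsC, ChPiParamsH, cross_pair_table
from conftest import apply_rigid, make_structure, random_rigid_motion


class TestAngularFactor:
    def test_endpoints(self):
        assert f_theta(0.0) == 1.0
        assert f_theta(90.0) == 0.0
        assert f_theta(120.0) == 0.0

    def test_cosine_value(self):
        assert np.isclose(f_theta(60.0), 0.5)

    def test_strictly_decreasing_on_0_90(self):
        xs = np.linspace(0, 90, 91)
        ys = [f_theta(x) for x in xs]
        assert all(a > b for a, b in zip(ys, ys[1:]))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            f_theta(-1.0)
        with pytest.raises(ValueError):
            f_theta(181.0)


def lone_aromatic_carbon(at):
    """A one-carbon 'ring' stub for per-pair checks."""
    ring = AromaticRing((0,), centroid=np.asarray(at, float),
                        normal=np.array([0.0, 0.0, 1.0]), ring_carbons=(0,))
    return ring, [np.asarray(at, float).reshape(1, 3)]


class TestChPiForms:
    def test_h_pair_well_depth_at_optimum(self):
        p = ChPiParamsH()
        ring, coords = lone_aromatic_carbon((0, 0, 0))
        h = np.array([0.0, 0.0, p.r0])
        c = h + np.array([0.0, 0.0, 1.09])
        e = e_chpi_h([(c, h)], [ring], p, ring_coords=coords)
        # per-pair well depth is E_HC times the 1/2 pi-lobe factor
        assert np.isclose(e, -p.e * PAIR_SCALE, atol=1e-12)

    def test_h_pair_zero_at_perpendicular_tilt(self):
        p = ChPiParamsH()
        ring, coords = lone_aromatic_carbon((0, 0, 0))
        h = np.array([0.0, 0.0, p.r0])
        c = h + np.array([1.09, 0.0, 0.0])  # C-H parallel to the ring plane
        assert e_chpi_h([(c, h)], [ring], p, ring_coords=coords) == 0.0

    def test_c_pair_well_depth_and_cutoff(self):
        p = ChPiParamsC()
        ring, coords = lone_aromatic_carbon((0, 0, 0))
        e = e_chpi_c([np.array([0.0, 0.0, p.r0])], [ring], p, ring_coords=coords)
        assert np.isclose(e, -p.e * PAIR_SCALE, atol=1e-12)
        far = e_chpi_c([np.array([0.0, 0.0, 10.0])], [ring], p, ring_coords=coords)
        assert far == 0.0

    def test_methane_rotation_symmetry_h_independent(self):
        from scipy.spatial.transform import Rotation

        vals = []
        for az in (0, 25, 111, 290):
            benzene, methane = build_dimer(DimerSpec("A", 3.8))
            rot = Rotation.from_euler("z", az, degrees=True).as_matrix()
            for a in methane.atoms:
                a.coords = rot @ (a.coords - [0, 0, 3.8]) + [0, 0, 3.8]
            vals.append(total_energy(benzene, methane, w=1.0, mode="hindep").e_chpi)
        assert np.allclose(vals, vals[0], atol=1e-12)

    def test_never_positive_and_decaying(self):
        for mode in ("hdep", "hindep"):
            for rv in np.arange(3.0, 8.0, 0.5):
                bz, mt = build_dimer(DimerSpec("C", rv))
                e = total_energy(bz, mt, w=1.0, mode=mode).e_chpi
                assert e <= 0.0
        tail = [total_energy(*build_dimer(DimerSpec("A", rv)), w=1.0).e_chpi
                for rv in (4.6, 5.2, 5.8, 6.4, 7.0)]
        assert all(a < b for a, b in zip(tail, tail[1:]))  # monotone to zero


class TestBaseScore:
    def test_two_hydrophobic_carbons_at_contact(self):
        rec = make_structure([("C1", "C", (0, 0, 0))])
        lig = make_structure([("C1", "C", (3.8, 0, 0))])  # surface distance 0
        e = vina_base_energy(rec, lig)
        w = BASE_PARAMS["weights"]
        expected = (w["gauss1"] + w["gauss2"] * math.exp(-((0 - 3) / 2) ** 2)
                    + w["hydrophobic"])
        assert np.isclose(e, expected, atol=1e-12)

    def test_cutoff_at_8A(self):
        rec = make_structure([("C1", "C", (0, 0, 0))])
        lig = make_structure([("C1", "C", (9.0, 0, 0))])
        assert vina_base_energy(rec, lig) == 0.0

    def test_repulsion_inside_contact(self):
        rec = make_structure([("C1", "C", (0, 0, 0))])
        lig = make_structure([("C1", "C", (3.3, 0, 0))])  # d = -0.5
        w = BASE_PARAMS["weights"]
        e = vina_base_energy(rec, lig)
        assert e > w["gauss1"] + w["hydrophobic"] + w["repulsion"] * 0.25 - 0.01

    def test_hbond_donor_acceptor_pair(self):
        rec = make_structure([("N1", "N", (0, 0, 0)), ("H1", "H", (1.0, 0, 0))])
        lig = make_structure([("O1", "O", (0, 0, 2.8))])  # d = -0.7
        e_hb = vina_base_energy(rec, lig)
        lig2 = make_structure([("C1", "C", (0, 0, 2.8))])
        e_cc = vina_base_energy(rec, lig2)
        assert e_hb < e_cc  # the donor-acceptor pair gains the H-bond term

    def test_untyped_structure_rejected(self):
        rec = make_structure([("C1", "C", (0, 0, 0))], typed=False)
        lig = make_structure([("C1", "C", (4, 0, 0))])
        with pytest.raises(ValueError):
            vina_base_energy(rec, lig)


class TestTotalEnergy:
    def test_w0_equals_base_bitwise(self):
        bz, mt = build_dimer(DimerSpec("B", 3.6))
        bd = total_energy(bz, mt, w=0.0, mode="hdep")
        assert bd.total == vina_base_energy(bz, mt)
        assert bd.total == bd.e_base

    def test_breakdown_identity(self):
        bz, mt = build_dimer(DimerSpec("C", 3.9))
        for w in (0.0, 0.3, 0.7, 1.0):
            bd = total_energy(bz, mt, w=w)
            assert abs(bd.total - (bd.e_base + w * bd.e_chpi)) < 1e-9
            assert bd.e_chpi <= 0.0

    def test_infinite_separation_is_zero(self):
        bz, mt = build_dimer(DimerSpec("A", 30.0))
        assert total_energy(bz, mt, w=1.0).total == 0.0

    def test_w_domain_error(self):
        bz, mt = build_dimer(DimerSpec("A", 3.8))
        with pytest.raises(ValueError):
            total_energy(bz, mt, w=1.2)
        with pytest.raises(ValueError):
            total_energy(bz, mt, w=-0.1)

    def test_rigid_motion_invariance(self, rng):
        bz, mt = build_dimer(DimerSpec("F", 3.7))
        ref = total_energy(bz, mt, w=1.0, mode="hdep")
        for _ in range(5):
            rot, t = random_rigid_motion(rng)
            bd = total_energy(apply_rigid(bz, rot, t), apply_rigid(mt, rot, t),
                              w=1.0, mode="hdep")
            assert np.isclose(bd.total, ref.total, atol=1e-6)
            assert np.isclose(bd.e_chpi, ref.e_chpi, atol=1e-6)

    def test_hdep_hindep_shapes_agree_for_ade(self):
        """Where the ring-facing C-H has f(theta2)=1, dropping the angular
        factor leaves a curve of similar shape over the attractive range."""
        for geom in ("A", "D", "E"):
            rvs = np.arange(3.6, 6.01, 0.2)
            eh = np.array([total_energy(*build_dimer(DimerSpec(geom, rv)), w=1.0,
                                        mode="hdep").e_chpi for rv in rvs])
            ec = np.array([total_energy(*build_dimer(DimerSpec(geom, rv)), w=1.0,
                                        mode="hindep").e_chpi for rv in rvs])
            # same sign, same order of magnitude, minima within 0.4 A
            assert np.corrcoef(eh, ec)[0, 1] > 0.97
            assert abs(rvs[np.argmin(eh)] - rvs[np.argmin(ec)]) <= 0.4

    def test_pairwise_sum_matches_brute_force_oracle(self):
        bz, mt = build_dimer(DimerSpec("E", 3.7))
        bd = total_energy(bz, mt, w=1.0, mode="hdep")
        # independent oracle: explicit loop over H/ring-carbon pairs
        p = ChPiParamsH()
        rings = perceive_aromatic_rings(bz)
        table = mt.neighbor_table()
        acc = 0.0
        for i, at in enumerate(mt.atoms):
            if at.docking_type != "aliphatic-carbon":
                continue
            for j in table[i]:
                if not mt.atoms[j].is_hydrogen:
                    continue
                u = mt.atoms[j].coords - at.coords
                u /= np.linalg.norm(u)
                for ring in rings:
                    n = ring.normal
                    if np.dot(n, ring.centroid - at.coords) < 0:
                        n = -n
                    f = max(float(np.dot(u, n)), 0.0)
                    for k in ring.ring_carbons:
                        r = np.linalg.norm(bz.atoms[k].coords - mt.atoms[j].coords)
                        if r < 8.0:
                            acc -= p.e * 0.5 * f * math.exp(-((r - p.r0) ** 2) / p.c)
        assert np.isclose(bd.e_chpi, acc, atol=1e-12)

    def test_missing_hydrogens_rejected_in_hdep(self):
        bz, mt = build_dimer(DimerSpec("A", 3.8))
        bare = make_structure([("C1", "C", (0, 0, 3.8))])
        with pytest.raises(ValueError, match="hydrogens"):
            total_energy(bz, bare, w=1.0, mode="hdep")
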