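"""Pose prediction by torsion grid search, with and without the CH-pi term.

A two-substituent rotor (one aliphatic C-H, one ether oxygen) sits above a
benzene ring, with a cluster of N-H donors to one side.  Scoring every 3-deg
rotamer with the base score alone picks the decoy pose that hydrogen-bonds
the oxygen to the donors; adding the CH-pi term at w = 0.7 flips the winner
back to the crystallographic-style pose with the C-H over the ring face --
the same failure mode and rescue seen for hydroxyl-decoy ligands in
experimental complexes.
"""

import numpy as np

from chpi import RotatableBond, best_rotamer
from chpi.structure import Atom, Structure
from chpi.atomtyping import assign_atom_types
from chpi.structure import infer_bonds

TET = 109.4712206
HEIGHT = 4.6


def build_pair():
    c2 = np.array([0.0, 0.0, HEIGHT])
    c1 = c2 + np.array([1.54, 0.0, 0.0])

    def sub(beta_deg, length):
        b = np.deg2rad(beta_deg)
        d = np.array([np.cos(np.deg2rad(TET)),
                      np.sin(np.deg2rad(TET)) * np.cos(b),
                      np.sin(np.deg2rad(TET)) * np.sin(b)])
        return c2 + length * d

    lig_atoms = [
        Atom(1, "C1", "C", c1), Atom(2, "C2", "C", c2),
        Atom(3, "H1", "H", sub(-90, 1.09)), Atom(4, "O1", "O", sub(90, 1.43)),
    ]
    ligand = assign_atom_types(Structure(lig_atoms, bonds=[(0, 1), (1, 2), (1, 3)]))

    rec_atoms = []
    for k in range(6):
        a = np.deg2rad(60 * k)
        rec_atoms.append(Atom(k + 1, f"C{k+1}", "C",
                              np.array([1.391 * np.cos(a), 1.391 * np.sin(a), 0.0]),
                              residue_name="PHE"))
    o_target = np.array([-0.477, 1.348, HEIGHT])
    serial = 7
    for d in ([0.0, 1.0, 0.0], [0.766, 0.643, 0.0], [-0.766, 0.643, 0.0]):
        n = o_target + 3.3 * np.asarray(d)
        rec_atoms.append(Atom(serial, f"N{serial}", "N", n, residue_name="ASN"))
        rec_atoms.append(Atom(serial + 1, f"H{serial}", "H", n + [0.0, 0.9, 0.0],
                              residue_name="ASN"))
        serial += 2
    receptor = assign_atom_types(Structure(rec_atoms, bonds=infer_bonds(rec_atoms)))
    return receptor, ligand


receptor, ligand = build_pair()
bond = RotatableBond(axis_atoms=(0, 1), moving_set=(2, 3))

for w in (0.0, 0.7):
    res = best_rotamer(receptor, ligand, [bond], w=w, mode="hdep")
    print(f"w = {w:.1f}: best torsion {res.best_angles[0]:6.1f} deg  "
          f"total {res.best_breakdown.total:7.3f}  "
          f"chpi {res.best_breakdown.e_chpi:7.3f} kcal/mol  "
          f"({res.n_scored}/{res.n_enumerated} rotamers clash-free)")
print("\nangle 0 deg is the reference pose with the C-H over the ring;")
print("~90 deg is the hydrogen-bond decoy.")
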