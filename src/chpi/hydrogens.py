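"""Ideal-geometry completion of aliphatic hydrogens.

Crystal structures (and many docking inputs) omit nonpolar hydrogens, but the
hydrogen-dependent CH-pi energy and the contact detector both need them.  Each
sp3 carbon is completed to four substituents with hydrogens at the ideal
tetrahedral geometry and a C-H bond length of 1.09 A.  Existing hydrogens are
never moved; the operation is idempotent.

sp3 perception is geometric: a carbon is treated as sp3 unless it sits in a
perceived aromatic ring or has a short (<1.30 A) bond to N/O, the signature of
a double bond at crystallographic resolution.
"""

from __future__ import annotations

import numpy as np

from .structure import Atom, Structure, HYDROGEN

__all__ = ["add_aliphatic_hydrogens", "ValenceError"]

CH_BOND = 1.09          # built C-H bond length, A
TETRA = 109.4712206     # ideal tetrahedral angle, degrees


class ValenceError(ValueError):
    """A carbon carries more than four bonds."""


def _local_frame(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``v`` and each other."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(v, e1)


def _tetrahedral_directions(existing: list[np.ndarray], stagger_ref: np.ndarray | None) -> list[np.ndarray]:
    """Unit vectors completing ``existing`` bond directions to a tetrahedron."""
    k = len(existing)
    cos_t = np.cos(np.deg2rad(TETRA))
    sin_t = np.sin(np.deg2rad(TETRA))
    if k == 0:
        # free methane-like carbon: canonical tetrahedron
        out = [np.array([0.0, 0.0, 1.0])]
        for phi in (0.0, 120.0, 240.0):
            p = np.deg2rad(phi)
            out.append(np.array([sin_t * np.cos(p), sin_t * np.sin(p), cos_t]))
        return out
    if k == 1:
        v = existing[0]
        e1, e2 = _local_frame(v)
        if stagger_ref is not None:
            # place the first new bond anti-periplanar to the reference
            # substituent on the neighbouring atom (staggered rotamer)
            w = stagger_ref - np.dot(stagger_ref, v) * v
            n = np.linalg.norm(w)
            if n > 1e-8:
                e1 = -w / n
                e2 = np.cross(v, e1)
        out = []
        for phi in (0.0, 120.0, 240.0):
            p = np.deg2rad(phi)
            d = cos_t * v + sin_t * (np.cos(p) * e1 + np.sin(p) * e2)
            out.append(d / np.linalg.norm(d))
        return out
    if k == 2:
        bis = -(existing[0] + existing[1])
        bis /= np.linalg.norm(bis)
        perp = np.cross(existing[0], existing[1])
        perp /= np.linalg.norm(perp)
        half = np.deg2rad(TETRA) / 2.0
        out = []
        for sgn in (1.0, -1.0):
            d = np.cos(half) * bis + sgn * np.sin(half) * perp
            out.append(d / np.linalg.norm(d))
        return out
    if k == 3:
        d = -(existing[0] + existing[1] + existing[2])
        n = np.linalg.norm(d)
        if n < 1e-8:  # planar arrangement; fall back to the plane normal
            d = np.cross(existing[1] - existing[0], existing[2] - existing[0])
            n = np.linalg.norm(d)
        return [d / n]
    return []


def _is_sp3_carbon(s: Structure, i: int, nbrs: list[int], aromatic_atoms: set[int]) -> bool:
    a = s.atoms[i]
    if a.element != "C" or i in aromatic_atoms:
        return False
    if len(nbrs) >= 4:
        return True
    for j in nbrs:
        b = s.atoms[j]
        if b.element in ("N", "O") and np.linalg.norm(a.coords - b.coords) < 1.30:
            return False  # carbonyl / imine carbon
    return True


def add_aliphatic_hydrogens(s: Structure) -> Structure:
    """Return a new structure with every sp3 carbon completed to CH/CH2/CH3/CH4.

    Methyl hydrogens are built staggered to the heaviest substituent on the
    vicinal atom.  Raises :class:`ValenceError` for carbons with more than four
    bonds.
    """
    from .rings import perceive_aromatic_rings  # local import: avoids a cycle

    out = s.copy()
    aromatic_atoms: set[int] = set()
    for ring in perceive_aromatic_rings(out):
        aromatic_atoms.update(ring.atom_indices)

    table = out.neighbor_table()
    next_serial = max((a.serial for a in out.atoms), default=0)
    masses = {"H": 1, "C": 12, "N": 14, "O": 16, "S": 32, "P": 31}

    for i, atom in enumerate(list(out.atoms)):
        nbrs = table[i]
        if atom.element == "C" and len(nbrs) > 4:
            raise ValenceError(f"carbon {atom.serial} has {len(nbrs)} bonds")
        if not _is_sp3_carbon(out, i, nbrs, aromatic_atoms):
            continue
        missing = 4 - len(nbrs)
        if missing <= 0:
            continue
        existing = []
        for j in nbrs:
            v = out.atoms[j].coords - atom.coords
            existing.append(v / np.linalg.norm(v))

        stagger_ref = None
        heavy_nbrs = [j for j in nbrs if not out.atoms[j].is_hydrogen]
        if len(nbrs) == 1 and heavy_nbrs:
            # heaviest substituent on the single heavy neighbour
            j = heavy_nbrs[0]
            cand = [k for k in table[j] if k != i]
            if cand:
                k = max(cand, key=lambda k: masses.get(out.atoms[k].element, 0))
                stagger_ref = out.atoms[k].coords - out.atoms[j].coords

        for d in _tetrahedral_directions(existing, stagger_ref)[:missing]:
            next_serial += 1
            h = Atom(
                serial=next_serial,
                name=f"H{len(out.atoms)}",
                element="H",
                coords=atom.coords + CH_BOND * d,
                occupancy=atom.occupancy,
                b_factor=atom.b_factor,
                residue_name=atom.residue_name,
                residue_id=atom.residue_id,
                chain_id=atom.chain_id,
                docking_type=HYDROGEN,
            )
            out.atoms.append(h)
            out.bonds.append((i, len(out.atoms) - 1))
            table.append([i])
            table[i].append(len(out.atoms) - 1)
    return out
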