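"""Aromatic ring perception and the ring frame (centroid + normal).

Standard aromatic side chains are located by residue template (PHE/TYR benzene,
HIS imidazole, and the TRP indole treated as two independent rings, 5- and
6-membered, each with its own centroid).  Everything else -- ligands and
non-standard residues -- goes through cycle perception on the bond graph with a
planarity test: a 5- or 6-membered cycle is accepted as aromatic when no ring
atom deviates from the best-fit plane by more than 0.2 A and the ring is built
from C/N/O/S.  A chair cyclohexane fails the planarity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structure import Structure

__all__ = ["AromaticRing", "perceive_aromatic_rings", "ring_frame"]

PLANARITY_TOL = 0.2  # A, max out-of-plane deviation

# atom names listed in ring-path order (consecutive entries are bonded)
_TEMPLATES: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
}


@dataclass
class AromaticRing:
    """A planar 5/6-ring with its centroid and unit normal."""

    atom_indices: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray
    ring_carbons: tuple[int, ...]
    parent: str = "ligand"

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if n < 1e-10:
            raise ValueError("degenerate ring normal")
        self.normal = self.normal / n

    def __len__(self) -> int:
        return len(self.atom_indices)


def ring_frame(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid, unit normal (least-squares plane) and the maximum
    out-of-plane deviation of a ring's atom coordinates."""
    centroid = coords.mean(axis=0)
    x = coords - centroid
    # normal = singular vector of the smallest singular value
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    normal = vt[-1]
    dev = float(np.max(np.abs(x @ normal)))
    return centroid, normal, dev


def _ring_from_indices(s: Structure, idx: list[int], parent: str) -> AromaticRing | None:
    coords = np.array([s.atoms[i].coords for i in idx])
    centroid, normal, dev = ring_frame(coords)
    if dev > PLANARITY_TOL:
        return None
    carbons = tuple(i for i in idx if s.atoms[i].element == "C")
    return AromaticRing(tuple(idx), centroid, normal, carbons, parent)


def perceive_aromatic_rings(s: Structure) -> list[AromaticRing]:
    """All aromatic rings in ``s`` (template residues first, then perceived
    cycles).  Returns an empty list when there are none."""
    rings: list[AromaticRing] = []
    claimed: set[frozenset[int]] = set()

    by_res = s.residues()
    for (chain, resid, resname), indices in by_res.items():
        for template in _TEMPLATES.get(resname, []):
            names = {s.atoms[i].name: i for i in indices}
            if not all(n in names for n in template):
                continue
            idx = [names[n] for n in template]
            ring = _ring_from_indices(s, idx, parent=f"{resname}{resid}:{chain}")
            if ring is not None:
                rings.append(ring)
                claimed.add(frozenset(idx))

    g = nx.Graph()
    g.add_nodes_from(range(len(s.atoms)))
    g.add_edges_from(s.bonds)
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6) or frozenset(cycle) in claimed:
            continue
        if any(s.atoms[i].element not in ("C", "N", "O", "S") for i in cycle):
            continue
        # require every ring atom to be unsaturated-compatible: an sp3 CH2
        # carbon (two ring bonds + 2 H) is allowed only if the ring is planar,
        # so the planarity test is the decisive criterion.
        ordered = _order_cycle(cycle, g)
        if ordered is None:
            continue
        ring = _ring_from_indices(s, ordered, parent=_cycle_parent(s, ordered))
        if ring is not None:
            rings.append(ring)
            claimed.add(frozenset(ordered))
    return rings


def _order_cycle(cycle: list[int], g: nx.Graph) -> list[int] | None:
    """Order cycle atoms along the ring bond path."""
    sub = g.subgraph(cycle)
    if any(d != 2 for _, d in sub.degree):
        return None  # fused/bridged: keep only simple cycles from the basis
    start = cycle[0]
    ordered = [start]
    prev = None
    cur = start
    while len(ordered) < len(cycle):
        nxt = [n for n in sub.neighbors(cur) if n != prev]
        if not nxt:
            return None
        prev, cur = cur, nxt[0]
        ordered.append(cur)
    return ordered


def _cycle_parent(s: Structure, idx: list[int]) -> str:
    a = s.atoms[idx[0]]
    if a.residue_name in ("UNK", "LIG", "") or s.source_format == "internal":
        return "ligand"
    return f"{a.residue_name}{a.residue_id}:{a.chain_id}"
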