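"""Docking atom-type assignment.

The base pairwise score distinguishes hydrophobic carbons, aromatic carbons,
and polar atoms with hydrogen-bond donor/acceptor capability.  Assignment
follows the convention of the original docking score: a carbon is hydrophobic
unless bonded to a heteroatom; nitrogen is a donor when it carries a hydrogen
and an acceptor otherwise (ring nitrogens keep a dedicated tag so the CH-pi
energy can exclude them from the aromatic-carbon sum); oxygen is always an
acceptor and a donor when protonated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .rings import perceive_aromatic_rings
from .structure import (
    ALIPHATIC_C,
    AROMATIC_C,
    HYDROGEN,
    OTHER,
    POLAR,
    RING_N,
    Structure,
)

__all__ = ["assign_atom_types", "XSProperties", "xs_properties"]

# van der Waals radii of the base score, A
XS_RADII = {
    "C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1, "F": 1.5,
    "CL": 1.8, "BR": 2.0, "I": 2.2,
}
DEFAULT_RADIUS = 1.2  # metals / other


@dataclass(frozen=True)
class XSProperties:
    """Pairwise-score properties of one heavy atom."""

    radius: float
    hydrophobic: bool
    donor: bool
    acceptor: bool


def assign_atom_types(s: Structure) -> Structure:
    """Return a copy of ``s`` with ``docking_type`` set on every atom.

    Unknown elements are tagged ``other``; the operation is invariant under
    atom reordering because it only looks at local connectivity and ring
    membership.
    """
    out = s.copy()
    aromatic: set[int] = set()
    for ring in perceive_aromatic_rings(out):
        aromatic.update(ring.atom_indices)
    table = out.neighbor_table()
    for i, a in enumerate(out.atoms):
        if a.element == "H":
            a.docking_type = HYDROGEN
        elif a.element == "C":
            a.docking_type = AROMATIC_C if i in aromatic else ALIPHATIC_C
        elif a.element == "N":
            a.docking_type = RING_N if i in aromatic else POLAR
        elif a.element in ("O", "S", "P", "F", "CL", "BR", "I"):
            a.docking_type = POLAR
        else:
            a.docking_type = OTHER
    out.annotations["typed"] = True
    out.annotations["neighbor_table"] = table
    return out


def xs_properties(s: Structure, i: int, table: list[list[int]] | None = None) -> XSProperties:
    """Radius, hydrophobicity and donor/acceptor flags for heavy atom ``i``."""
    a = s.atoms[i]
    if table is None:
        table = s.neighbor_table()
    nbr_elements = [s.atoms[j].element for j in table[i]]
    el = a.element
    radius = XS_RADII.get(el, DEFAULT_RADIUS)
    if el == "C":
        hydrophobic = not any(e not in ("C", "H") for e in nbr_elements)
        return XSProperties(radius, hydrophobic, False, False)
    if el == "N":
        has_h = "H" in nbr_elements
        return XSProperties(radius, False, donor=has_h, acceptor=not has_h or len(nbr_elements) <= 2)
    if el == "O":
        has_h = "H" in nbr_elements
        return XSProperties(radius, False, donor=has_h, acceptor=True)
    if el in ("F", "CL", "BR", "I"):
        return XSProperties(radius, True, False, False)
    return XSProperties(radius, False, False, False)
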