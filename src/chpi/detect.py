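"""CH-pi contact detection and summary statistics.

A contact exists when an aliphatic hydrogen lies within 3.5 A of an aromatic
ring centroid.  Detection mirrors the filters used in crystallographic data
mining: residues containing any partial-occupancy atom or whose average
B-factor exceeds 40 A^2 are excluded (the ligand counts as one residue), and
methyl hydrogens are excluded because their rotational positions are not
experimentally determined.  Both directions are examined: ligand C-H against
receptor rings and receptor C-H against ligand rings.  Contacts with
theta1 < 35 deg and theta2 < 35 deg are flagged as strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import ChPiGeometry, chpi_geometry
from .rings import AromaticRing, perceive_aromatic_rings
from .structure import Structure

__all__ = ["ChPiContact", "detect_contacts", "summarize_contacts", "UnprotonatedError"]

STRONG_THETA = 35.0  # deg, theta1/theta2 bound for the strong subset


class UnprotonatedError(ValueError):
    """Aliphatic carbons lack the explicit hydrogens detection needs."""


@dataclass
class ChPiContact:
    ch_carbon: int
    ch_hydrogen: int
    ch_side: str            # "ligand" or "receptor"
    ring: AromaticRing
    geometry: ChPiGeometry
    passed_strong: bool


def _excluded_residues(s: Structure, max_b: float, whole_is_one: bool) -> set:
    """Residue keys failing the occupancy / B-factor filters."""
    out = set()
    groups = (
        {("*", 0, "*"): list(range(len(s.atoms)))} if whole_is_one else s.residues()
    )
    for key, idx in groups.items():
        atoms = [s.atoms[i] for i in idx]
        if any(a.partial_occupancy for a in atoms):
            out.add(key)
        elif np.mean([a.b_factor for a in atoms]) > max_b:
            out.add(key)
    return out


def _residue_key(s: Structure, i: int, whole_is_one: bool):
    if whole_is_one:
        return ("*", 0, "*")
    a = s.atoms[i]
    return (a.chain_id, a.residue_id, a.residue_name)


def _ch_groups(s: Structure, exclude_methyl: bool) -> list[tuple[int, int]]:
    """(carbon, hydrogen) pairs eligible for detection."""
    table = s.neighbor_table()
    pairs = []
    missing: list[int] = []
    for i, a in enumerate(s.atoms):
        if a.docking_type != "aliphatic-carbon":
            continue
        hs = [j for j in table[i] if s.atoms[j].is_hydrogen]
        heavy = [j for j in table[i] if not s.atoms[j].is_hydrogen]
        if not hs:
            if len(heavy) < 4 and not _looks_sp2(s, i, heavy):
                missing.append(i)
            continue
        if exclude_methyl and len(hs) == 3 and len(heavy) == 1:
            continue
        pairs.extend((i, j) for j in hs)
    if missing:
        names = ", ".join(f"{s.atoms[i].name}#{s.atoms[i].serial}" for i in missing[:8])
        raise UnprotonatedError(
            f"aliphatic carbons without hydrogens: {names}; run add_aliphatic_hydrogens"
        )
    return pairs


def _looks_sp2(s: Structure, i: int, heavy: list[int]) -> bool:
    a = s.atoms[i]
    return any(
        s.atoms[j].element in ("N", "O")
        and np.linalg.norm(a.coords - s.atoms[j].coords) < 1.30
        for j in heavy
    )


def detect_contacts(
    receptor: Structure,
    ligand: Structure,
    max_r: float = 3.5,
    max_b: float = 40.0,
    exclude_methyl: bool = True,
) -> list[ChPiContact]:
    """All CH-pi contacts between two typed, protonated structures."""
    contacts: list[ChPiContact] = []
    sides = (
        ("ligand", ligand, receptor, True, False),
        ("receptor", receptor, ligand, False, True),
    )
    for side, ch_struct, ring_struct, ch_is_ligand, ring_is_ligand in sides:
        rings = perceive_aromatic_rings(ring_struct)
        if not rings:
            continue
        bad_ring_res = _excluded_residues(ring_struct, max_b, whole_is_one=ring_is_ligand)
        bad_ch_res = _excluded_residues(ch_struct, max_b, whole_is_one=ch_is_ligand)
        rings = [
            r for r in rings
            if _residue_key(ring_struct, r.atom_indices[0], ring_is_ligand) not in bad_ring_res
        ]
        pairs = [
            (c, h) for c, h in _ch_groups(ch_struct, exclude_methyl)
            if _residue_key(ch_struct, c, ch_is_ligand) not in bad_ch_res
        ]
        for ring in rings:
            ring_xyz = np.array([ring_struct.atoms[i].coords for i in ring.atom_indices])
            for c, h in pairs:
                h_xyz = ch_struct.atoms[h].coords
                if np.linalg.norm(h_xyz - ring.centroid) > max_r:
                    continue
                geo = chpi_geometry(
                    ch_struct.atoms[c].coords, h_xyz, ring, ring_carbon_coords=ring_xyz
                )
                contacts.append(
                    ChPiContact(
                        ch_carbon=c,
                        ch_hydrogen=h,
                        ch_side=side,
                        ring=ring,
                        geometry=geo,
                        passed_strong=geo.theta1 < STRONG_THETA and geo.theta2 < STRONG_THETA,
                    )
                )
    return contacts


def summarize_contacts(contacts: list[ChPiContact]) -> dict:
    """Descriptor statistics: mean +/- sd per descriptor, histograms, counts
    per ring parent, and the face-folded poses used for aggregation.

    CH coordinates are reflected to one ring face (vertical offsets taken
    positive) before aggregation, so mirror-image contacts aggregate to the
    same pose.  An empty input returns ``{"empty": True}``.
    """
    if not contacts:
        return {"empty": True}
    rows = [c.geometry.as_dict() for c in contacts]
    df = pd.DataFrame(rows)
    stats = df.agg(["mean", "std"]).T
    stats["std"] = stats["std"].fillna(0.0)
    hists = {
        k: np.histogram(df[k], bins=18)
        for k in ("theta", "omega", "theta2", "C_centroid")
    }
    parents = pd.Series(
        [_parent_type(c.ring.parent) for c in contacts]
    ).value_counts().to_dict()
    poses = df[["R_H_H", "R_V_H", "R_H", "R_V"]].round(6)
    return {
        "empty": False,
        "n": len(contacts),
        "stats": stats,
        "histograms": hists,
        "counts_by_parent": parents,
        "poses": poses,
    }


def _parent_type(parent: str) -> str:
    if parent == "ligand":
        return "ligand"
    for resname in ("PHE", "TYR", "TRP", "HIS"):
        if parent.startswith(resname):
            return resname
    return parent.rstrip("0123456789:ABCDEFGHIJKLMNOPQRSTUVWXYZ") or parent
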