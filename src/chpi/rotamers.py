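"""Torsion grid search over ligand-moiety or side-chain rotamers.

Up to two rotatable bonds are scanned from 0 to 360 deg in 3 deg increments
(120^n conformations).  Conformations with severe intramolecular clashes are
discarded using inclusive distance thresholds -- 2.0 A between heavy atoms,
1.75 A between a heavy atom and a hydrogen, 1.40 A between hydrogens -- with
1-2 and 1-3 bonded pairs exempt (1-4 pairs are checked).  Every surviving
rotamer is scored against the receptor with the combined score; the winner is
the most negative total.  Accuracy versus a reference pose is reported as the
heavy-atom rmsd of the moving set (no re-superposition: the receptor frame is
fixed) and as per-bond angular deviations wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.spatial.transform import Rotation

from .scoring import EnergyBreakdown, total_energy
from .structure import Structure

__all__ = [
    "RotatableBond",
    "RotamerResult",
    "NoValidRotamerError",
    "enumerate_rotamers",
    "clash_filter",
    "best_rotamer",
    "CLASH_HEAVY_HEAVY",
    "CLASH_HEAVY_H",
    "CLASH_H_H",
]

CLASH_HEAVY_HEAVY = 2.0   # A, inclusive
CLASH_HEAVY_H = 1.75
CLASH_H_H = 1.40
GRID_STEP = 3.0           # deg


class NoValidRotamerError(RuntimeError):
    """Every enumerated conformation failed the clash filter."""


@dataclass(frozen=True)
class RotatableBond:
    """A torsion axis and the atom set it rotates."""

    axis_atoms: tuple[int, int]
    moving_set: tuple[int, ...]
    kind: str = "ligand-moiety"   # or "side-chain chi1" / "side-chain chi2"

    def __post_init__(self) -> None:
        if not self.moving_set:
            raise ValueError("empty moving set")
        if any(a in self.moving_set for a in self.axis_atoms):
            raise ValueError("axis atoms may not be in the moving set")


@dataclass
class RotamerResult:
    best_angles: tuple[float, ...]
    best_breakdown: EnergyBreakdown
    rmsd_to_reference: float
    angle_deviation: tuple[float, ...]
    n_enumerated: int
    n_scored: int


def _rotate(coords: np.ndarray, bond: RotatableBond, angle_deg: float) -> np.ndarray:
    """Rotate the bond's moving set about its (current) axis."""
    a, b = bond.axis_atoms
    axis = coords[b] - coords[a]
    n = np.linalg.norm(axis)
    if n < 1e-8:
        raise ValueError("degenerate rotation axis")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n)
    out = coords.copy()
    idx = list(bond.moving_set)
    out[idx] = rot.apply(coords[idx] - coords[a]) + coords[a]
    return out


def enumerate_rotamers(
    s: Structure,
    bonds: list[RotatableBond],
    step: float = GRID_STEP,
) -> Iterator[tuple[tuple[float, ...], Structure]]:
    """Lazily yield ``(angles, conformation)`` over the full torsion grid.

    Angles run 0, step, ..., 360-step per bond (120^n conformations at the
    3 deg default); the input structure is never modified and the (0, ..., 0)
    conformation equals it exactly.
    """
    n = len(bonds)
    if not 1 <= n <= 2:
        raise ValueError(f"need 1 or 2 rotatable bonds, got {n}")
    angles = np.arange(0.0, 360.0, step)
    base = s.coords

    def conformations(prefix: tuple[float, ...], coords: np.ndarray, depth: int):
        if depth == n:
            out = s.copy()
            for i, a in enumerate(out.atoms):
                a.coords = coords[i].copy()
            yield prefix, out
            return
        for ang in angles:
            yield from conformations(
                prefix + (float(ang),),
                _rotate(coords, bonds[depth], ang) if ang else coords,
                depth + 1,
            )

    yield from conformations((), base, 0)


def clash_filter(conformation: Structure) -> bool:
    """True (reject) iff any nonbonded pair violates the inclusive clash
    thresholds; 1-2 and 1-3 pairs are exempt."""
    coords = conformation.coords
    n = len(coords)
    if n < 2:
        return False
    table = conformation.neighbor_table()
    exempt: set[tuple[int, int]] = set()
    for i in range(n):
        for j in table[i]:
            exempt.add((min(i, j), max(i, j)))
            for k in table[j]:
                if k != i:
                    exempt.add((min(i, k), max(i, k)))
    is_h = np.array([a.is_hydrogen for a in conformation.atoms])
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in exempt:
                continue
            if is_h[i] and is_h[j]:
                lim = CLASH_H_H
            elif is_h[i] or is_h[j]:
                lim = CLASH_HEAVY_H
            else:
                lim = CLASH_HEAVY_HEAVY
            if d[i, j] <= lim:
                return True
    return False


def _wrap(delta: float) -> float:
    """Wrap an angular difference to (-180, 180]."""
    d = (delta + 180.0) % 360.0 - 180.0
    return 180.0 if d == -180.0 else d


def best_rotamer(
    receptor: Structure,
    ligand: Structure,
    bonds: list[RotatableBond],
    w: float = 0.7,
    mode: str = "hdep",
    reference: Structure | None = None,
    step: float = GRID_STEP,
) -> RotamerResult:
    """Exhaustive torsion grid search; returns the lowest-total rotamer.

    ``reference`` (default: the input ligand pose) supplies the experimental
    coordinates for the rmsd and angle-deviation report.  Ties in total
    energy break to the first (smallest) angle tuple.
    """
    reference = reference if reference is not None else ligand
    ref_coords = reference.coords
    moving = sorted({i for b in bonds for i in b.moving_set})
    heavy_moving = [i for i in moving if not ligand.atoms[i].is_hydrogen]

    best: tuple[tuple[float, ...], EnergyBreakdown, Structure] | None = None
    n_enum = n_scored = 0
    for angs, conf in enumerate_rotamers(ligand, bonds, step=step):
        n_enum += 1
        if clash_filter(conf):
            continue
        n_scored += 1
        bd = total_energy(receptor, conf, w=w, mode=mode)
        if best is None or bd.total < best[1].total:
            best = (angs, bd, conf)
    if best is None:
        raise NoValidRotamerError("all conformations failed the clash filter")

    angs, bd, conf = best
    diff = conf.coords[heavy_moving] - ref_coords[heavy_moving]
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))) if heavy_moving else 0.0
    deviation = tuple(_wrap(a) for a in angs)
    return RotamerResult(
        best_angles=angs,
        best_breakdown=bd,
        rmsd_to_reference=rmsd,
        angle_deviation=deviation,
        n_enumerated=n_enum,
        n_scored=n_scored,
    )
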