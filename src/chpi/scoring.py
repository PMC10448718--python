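r"""The base docking score and the empirical CH-pi energy terms.

Base score
----------
:func:`vina_base_energy` re-implements the published empirical pairwise score:
two attractive Gaussians plus a quadratic soft repulsion (steric), a
hydrophobic contact term, and a non-directional hydrogen-bond term, all
evaluated on heavy-atom *surface* distances ``d = r - R_i - R_j`` with an 8 A
cutoff and the published weights and van der Waals radii (see
``data/base_score.json``).  Conformation-independent constants and the
rotatable-bond affinity rescaling are omitted: only pose-dependent energy
matters here.

CH-pi term
----------
The CH-pi energy is a pairwise sum over aliphatic hydrogens and aromatic ring
*carbons* (ring nitrogens are excluded, which is why imidazole stacking comes
out weak).  Each pair contributes a single-well radial attraction scaled by a
cosine tilt factor:

    E_pair = -E_HC * 1/2 * exp(-(R - R0_HC)^2 / C_HC) * f(theta2)
    f(theta2) = max(cos theta2, 0)

where ``R`` is the H-to-ring-carbon distance, ``theta2`` the angle between the
C-H bond vector and the ring normal oriented *through* the ring (so a C-H
pointing straight at the ring face has theta2 = 0 and hydrogens pointing away
are clamped to zero contribution).  The 1/2 factor accounts for the two lobes
of each ring carbon's pi orbital: only the lobe facing the hydrogen is
engaged.  Radial arrangement and lobe factor are implementation constants
fixed by calibration against the methane-benzene dimer anchors (base-only
trace ~ -0.4 kcal/mol, combined trace ~ -1.0 kcal/mol at 3.8 A, averaged
vertical optimum 3.7 +/- 0.2 A at -1.2 +/- 0.2 kcal/mol) with the parameter
values E_HC = 0.29, R0_HC = 3.58 A, C_HC = 0.85.

The hydrogen-independent variant drops f(theta2) and runs over aliphatic
carbon / ring carbon distances with E_CC = 0.26, R0_CC = 4.49 A, c_CC = 0.75,
for use where hydrogens are unavailable (as in grid-based docking codes).

The combined score is ``total = E_base + w * E_chpi`` with an empirical
weighting factor ``w`` (1.0 during curve fitting, 0.3 recommended in general).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .atomtyping import xs_properties
from .rings import AromaticRing, perceive_aromatic_rings
from .structure import Structure

__all__ = [
    "ChPiParamsH",
    "ChPiParamsC",
    "EnergyBreakdown",
    "f_theta",
    "e_chpi_h",
    "e_chpi_c",
    "vina_base_energy",
    "total_energy",
    "ch_pairs_of",
    "BASE_PARAMS",
]

with resources.files("chpi.data").joinpath("base_score.json").open() as _fh:
    BASE_PARAMS = json.load(_fh)

_W = BASE_PARAMS["weights"]
_CUTOFF = BASE_PARAMS["cutoff"]
PAIR_SCALE = BASE_PARAMS["chpi"]["pair_scale"]
DEFAULT_WEIGHT = BASE_PARAMS["chpi"]["default_weight"]


@dataclass(frozen=True)
class ChPiParamsH:
    """Hydrogen-dependent CH-pi constants (kcal/mol, A, A^2)."""

    e: float = BASE_PARAMS["chpi"]["h_dependent"]["E"]
    r0: float = BASE_PARAMS["chpi"]["h_dependent"]["R0"]
    c: float = BASE_PARAMS["chpi"]["h_dependent"]["C"]

    def __post_init__(self) -> None:
        if min(self.e, self.r0, self.c) <= 0:
            raise ValueError("CH-pi parameters must be positive")


@dataclass(frozen=True)
class ChPiParamsC:
    """Hydrogen-independent CH-pi constants (kcal/mol, A, A^2)."""

    e: float = BASE_PARAMS["chpi"]["h_independent"]["E"]
    r0: float = BASE_PARAMS["chpi"]["h_independent"]["R0"]
    c: float = BASE_PARAMS["chpi"]["h_independent"]["C"]

    def __post_init__(self) -> None:
        if min(self.e, self.r0, self.c) <= 0:
            raise ValueError("CH-pi parameters must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Base score, CH-pi term, weighting factor and their combination."""

    e_base: float
    e_chpi: float
    w: float
    total: float

    def as_dict(self) -> dict:
        return {"e_base": self.e_base, "e_chpi": self.e_chpi, "w": self.w, "total": self.total}


# ---------------------------------------------------------------------------
# Angular factor
# ---------------------------------------------------------------------------

def f_theta(theta2_deg: float) -> float:
    """Cosine decay of the CH-pi attraction with the tilt angle.

    1 when the C-H vector is parallel to the ring normal (theta2 = 0), 0 at
    and beyond perpendicular (theta2 >= 90 deg), strictly decreasing between.
    """
    if not 0.0 <= theta2_deg <= 180.0:
        raise ValueError(f"theta2 = {theta2_deg} outside [0, 180] degrees")
    if theta2_deg >= 90.0:
        return 0.0
    return math.cos(math.radians(theta2_deg))


def _radial(r: np.ndarray, r0: float, c: float) -> np.ndarray:
    return np.exp(-((r - r0) ** 2) / c)


# ---------------------------------------------------------------------------
# CH-pi sums
# ---------------------------------------------------------------------------

def ch_pairs_of(s: Structure) -> list[tuple[int, int]]:
    """(carbon, hydrogen) index pairs for every aliphatic C-H bond in ``s``."""
    table = s.neighbor_table()
    pairs = []
    for i, a in enumerate(s.atoms):
        if a.docking_type != "aliphatic-carbon":
            continue
        for j in table[i]:
            if s.atoms[j].is_hydrogen:
                pairs.append((i, j))
    return pairs


def chpi_pair_table_h(
    ch_pairs: list[tuple[np.ndarray, np.ndarray]],
    rings: list[AromaticRing],
    ring_coords: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """(f, R) arrays over every contributing H / ring-carbon pair, such that
    the hydrogen-dependent energy is ``-E * 1/2 * sum(f * g(R))``."""
    fs: list[float] = []
    ds: list[float] = []
    for c_xyz, h_xyz in ch_pairs:
        u = h_xyz - c_xyz
        nu = np.linalg.norm(u)
        if nu < 1e-8:
            raise ValueError("degenerate C-H bond vector (missing hydrogen coordinates?)")
        u = u / nu
        for ring, carbons in zip(rings, ring_coords):
            if len(carbons) == 0:
                continue
            # normal oriented from the aliphatic carbon through the ring
            n = ring.normal if np.dot(ring.normal, ring.centroid - c_xyz) > 0 else -ring.normal
            f = max(float(np.dot(u, n)), 0.0)
            if f == 0.0:
                continue
            r = np.linalg.norm(carbons - h_xyz, axis=1)
            r = r[r < _CUTOFF]
            fs.extend([f] * len(r))
            ds.extend(r.tolist())
    return np.array(fs), np.array(ds)


def chpi_pair_table_c(
    aliph_carbons: list[np.ndarray],
    ring_coords: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """(f, R) arrays (f identically 1) for the hydrogen-independent sum."""
    ds: list[float] = []
    for c_xyz in aliph_carbons:
        for carbons in ring_coords:
            if len(carbons) == 0:
                continue
            r = np.linalg.norm(carbons - c_xyz, axis=1)
            ds.extend(r[r < _CUTOFF].tolist())
    return np.ones(len(ds)), np.array(ds)


def e_chpi_h(
    ch_pairs: list[tuple[np.ndarray, np.ndarray]],
    rings: list[AromaticRing],
    p: ChPiParamsH | None = None,
    ring_coords: list[np.ndarray] | None = None,
) -> float:
    """Hydrogen-dependent CH-pi energy (kcal/mol, always <= 0).

    ``ch_pairs`` holds (C coordinates, H coordinates) for each aliphatic C-H
    bond; ``ring_coords`` holds, per ring, the coordinates of its carbon
    atoms (parallel to ``rings``).
    """
    p = p or ChPiParamsH()
    if ring_coords is None:
        raise ValueError("ring_coords (per-ring carbon coordinates) required")
    f, d = chpi_pair_table_h(ch_pairs, rings, ring_coords)
    if len(d) == 0:
        return 0.0
    return float(-p.e * PAIR_SCALE * np.sum(f * _radial(d, p.r0, p.c)))


def e_chpi_c(
    aliph_carbons: list[np.ndarray],
    rings: list[AromaticRing],
    p: ChPiParamsC | None = None,
    ring_coords: list[np.ndarray] | None = None,
) -> float:
    """Hydrogen-independent CH-pi energy over aliphatic-C / ring-C distances."""
    p = p or ChPiParamsC()
    if ring_coords is None:
        raise ValueError("ring_coords (per-ring carbon coordinates) required")
    f, d = chpi_pair_table_c(aliph_carbons, ring_coords)
    if len(d) == 0:
        return 0.0
    return float(-p.e * PAIR_SCALE * np.sum(f * _radial(d, p.r0, p.c)))


# ---------------------------------------------------------------------------
# Base score
# ---------------------------------------------------------------------------

class TypingError(ValueError):
    """A structure was passed to the scorer without docking types."""


def _check_typed(s: Structure, label: str) -> None:
    if not s.annotations.get("typed"):
        raise TypingError(f"{label} structure has no docking types; call assign_atom_types first")


def vina_base_energy(receptor: Structure, ligand: Structure) -> float:
    """Intermolecular base score (kcal/mol) between two typed structures.

    Heavy atoms only; each pair within the 8 A surface-distance cutoff
    contributes the steric, hydrophobic and hydrogen-bond terms.
    """
    _check_typed(receptor, "receptor")
    _check_typed(ligand, "ligand")
    ri = receptor.heavy_indices()
    li = ligand.heavy_indices()
    if not ri or not li:
        return 0.0
    rt = receptor.annotations.get("neighbor_table") or receptor.neighbor_table()
    lt = ligand.annotations.get("neighbor_table") or ligand.neighbor_table()
    rprops = [xs_properties(receptor, i, rt) for i in ri]
    lprops = [xs_properties(ligand, i, lt) for i in li]
    rx = np.array([receptor.atoms[i].coords for i in ri])
    lx = np.array([ligand.atoms[i].coords for i in li])

    pairs = cKDTree(rx).query_ball_tree(cKDTree(lx), r=_CUTOFF)
    g1o, g1w = BASE_PARAMS["gauss1"]["offset"], BASE_PARAMS["gauss1"]["width"]
    g2o, g2w = BASE_PARAMS["gauss2"]["offset"], BASE_PARAMS["gauss2"]["width"]
    hg, hb = BASE_PARAMS["hydrophobic"]["good"], BASE_PARAMS["hydrophobic"]["bad"]
    bg, bb = BASE_PARAMS["hbond"]["good"], BASE_PARAMS["hbond"]["bad"]

    total = 0.0
    for a, blist in enumerate(pairs):
        pa = rprops[a]
        for b in blist:
            pb = lprops[b]
            r = float(np.linalg.norm(rx[a] - lx[b]))
            if r >= _CUTOFF:  # cutoff applies to the interatomic distance
                continue
            d = r - pa.radius - pb.radius
            e = _W["gauss1"] * math.exp(-(((d - g1o) / g1w) ** 2))
            e += _W["gauss2"] * math.exp(-(((d - g2o) / g2w) ** 2))
            if d < 0:
                e += _W["repulsion"] * d * d
            if pa.hydrophobic and pb.hydrophobic:
                e += _W["hydrophobic"] * _slide(d, hg, hb)
            if (pa.donor and pb.acceptor) or (pa.acceptor and pb.donor):
                e += _W["hbond"] * _slide(d, bg, bb)
            total += e
    return total


def _slide(d: float, good: float, bad: float) -> float:
    if d <= good:
        return 1.0
    if d >= bad:
        return 0.0
    return (bad - d) / (bad - good)


# ---------------------------------------------------------------------------
# Combined score
# ---------------------------------------------------------------------------

def _cross_chpi(receptor: Structure, ligand: Structure, mode: str,
                params) -> float:
    """CH-pi energy in both directions (ligand CH vs receptor rings and
    vice versa)."""
    e = 0.0
    for ch_side, ring_side in ((ligand, receptor), (receptor, ligand)):
        rings = perceive_aromatic_rings(ring_side)
        if not rings:
            continue
        ring_coords = [
            np.array([ring_side.atoms[i].coords for i in r.ring_carbons]).reshape(-1, 3)
            for r in rings
        ]
        if mode == "hdep":
            pairs = ch_pairs_of(ch_side)
            n_aliph = sum(1 for a in ch_side.atoms if a.docking_type == "aliphatic-carbon")
            if n_aliph and not pairs:
                raise ValueError(
                    "hydrogen-dependent mode needs explicit aliphatic hydrogens; "
                    "run add_aliphatic_hydrogens first"
                )
            coords = [(ch_side.atoms[c].coords, ch_side.atoms[h].coords) for c, h in pairs]
            e += e_chpi_h(coords, rings, params, ring_coords=ring_coords)
        else:
            carbons = [a.coords for a in ch_side.atoms if a.docking_type == "aliphatic-carbon"]
            e += e_chpi_c(carbons, rings, params, ring_coords=ring_coords)
    return e


def cross_pair_table(receptor: Structure, ligand: Structure, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Both-direction (f, R) pair table for a complex; the CH-pi energy for
    parameters (E, R0, c) is ``-E * 1/2 * sum(f * exp(-(R-R0)^2/c))``."""
    fs, ds = [np.empty(0)], [np.empty(0)]
    for ch_side, ring_side in ((ligand, receptor), (receptor, ligand)):
        rings = perceive_aromatic_rings(ring_side)
        if not rings:
            continue
        ring_coords = [
            np.array([ring_side.atoms[i].coords for i in r.ring_carbons]).reshape(-1, 3)
            for r in rings
        ]
        if mode == "hdep":
            pairs = ch_pairs_of(ch_side)
            coords = [(ch_side.atoms[c].coords, ch_side.atoms[h].coords) for c, h in pairs]
            f, d = chpi_pair_table_h(coords, rings, ring_coords)
        else:
            carbons = [a.coords for a in ch_side.atoms if a.docking_type == "aliphatic-carbon"]
            f, d = chpi_pair_table_c(carbons, ring_coords)
        fs.append(f)
        ds.append(d)
    return np.concatenate(fs), np.concatenate(ds)


def total_energy(
    receptor: Structure,
    ligand: Structure,
    w: float = DEFAULT_WEIGHT,
    mode: str = "hdep",
    params=None,
) -> EnergyBreakdown:
    """Base score plus weighted CH-pi term.

    ``mode`` selects the hydrogen-dependent (``"hdep"``) or
    hydrogen-independent (``"hindep"``) CH-pi form; ``w`` must lie in [0, 1]
    (1.0 during fitting, 0.3 recommended for general scoring).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"weighting factor w = {w} outside [0, 1]")
    if mode not in ("hdep", "hindep"):
        raise ValueError(f"unknown mode {mode!r}")
    if params is None:
        params = ChPiParamsH() if mode == "hdep" else ChPiParamsC()
    e_base = vina_base_energy(receptor, ligand)
    e_chpi = _cross_chpi(receptor, ligand, mode, params)
    return EnergyBreakdown(e_base=e_base, e_chpi=e_chpi, w=w, total=e_base + w * e_chpi)
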