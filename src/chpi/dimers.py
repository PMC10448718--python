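"""Idealized methane/benzene monomers, the six dimer geometries, energy
scans, and synthetic binding-site fixtures.

The six labeled dimer geometries place a methane above a benzene ring at a
vertical carbon-to-centroid distance ``R_V`` (optionally displaced
horizontally by ``R_H``).  Orientation conventions (implementation
constants -- the tetrahedral symmetry of methane leaves three distinct
axis-aligned orientations, distinguished further by azimuth):

====== ===========================================================
label  methane orientation
====== ===========================================================
A      one C-H toward the ring (vertex), azimuth 0 deg
D      vertex toward ring, azimuth 20 deg
E      vertex toward ring, azimuth 40 deg
B      face toward ring (three C-H tripod), azimuth 0 deg
C      edge toward ring (two C-H), azimuth 0 deg
F      face toward ring, azimuth 30 deg
====== ===========================================================

A, D and E form the family whose ring-facing C-H has f(theta2) = 1; they are
the geometries used when fitting the hydrogen-independent energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .atomtyping import assign_atom_types
from .structure import Atom, Structure, infer_bonds

__all__ = [
    "DimerSpec",
    "EnergyCurve",
    "build_monomer",
    "build_dimer",
    "scan_curve",
    "find_minimum",
    "make_synthetic_site",
    "VERTICAL_GRID",
    "horizontal_grid",
    "GEOMETRY_ORIENTATIONS",
]

BENZENE_CC = 1.391   # A
BENZENE_CH = 1.087
METHANE_CH = 1.091
TETRA = 109.4712206

# orientation (kind, azimuth_deg) per geometry label
GEOMETRY_ORIENTATIONS: dict[str, tuple[str, float]] = {
    "A": ("vertex", 0.0),
    "B": ("face", 0.0),
    "C": ("edge", 0.0),
    "D": ("vertex", 20.0),
    "E": ("vertex", 40.0),
    "F": ("face", 30.0),
}

# vertical scan: 0.1 A steps over 3.0-4.2, then 0.2 A steps to 6.0 (22 points)
VERTICAL_GRID = np.round(
    np.concatenate([np.arange(3.0, 4.2001, 0.1), np.arange(4.4, 6.0001, 0.2)]), 10
)


def horizontal_grid(direction: str, extended: bool = False) -> np.ndarray:
    """0.1 A horizontal-offset grid: to 1.4 A toward a ring carbon, to 1.2 A
    toward a C-C bond midpoint (or to 6.0 A when ``extended``)."""
    if direction == "toward-ring-carbon":
        top = 6.0 if extended else 1.4
    elif direction == "toward-bond-midpoint":
        top = 6.0 if extended else 1.2
    else:
        raise ValueError(f"unknown offset direction {direction!r}")
    return np.round(np.arange(0.0, top + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class DimerSpec:
    """One methane-benzene dimer placement."""

    geometry: str
    r_v: float
    r_h: float = 0.0
    offset_direction: str = "toward-bond-midpoint"

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRY_ORIENTATIONS:
            raise ValueError(f"geometry label {self.geometry!r} not in A-F")
        if self.r_v <= 0 or self.r_h < 0:
            raise ValueError("require r_v > 0 and r_h >= 0")
        if self.offset_direction not in ("toward-ring-carbon", "toward-bond-midpoint"):
            raise ValueError(f"unknown offset direction {self.offset_direction!r}")


@dataclass
class EnergyCurve:
    """Energies along a scan axis."""

    abscissa: np.ndarray
    energies: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float)
        self.energies = np.asarray(self.energies, float)
        if len(self.abscissa) != len(self.energies):
            raise ValueError("abscissa and energies differ in length")
        if np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing")


# ---------------------------------------------------------------------------
# Monomers
# ---------------------------------------------------------------------------

def build_monomer(kind: str) -> Structure:
    """Idealized benzene (planar D6h) or methane (Td), centered at the
    origin, typed and bonded."""
    atoms: list[Atom] = []
    if kind == "benzene":
        ang = np.deg2rad(np.arange(6) * 60.0)
        for k in range(6):
            c = np.array([BENZENE_CC * np.cos(ang[k]), BENZENE_CC * np.sin(ang[k]), 0.0])
            atoms.append(Atom(serial=k + 1, name=f"C{k+1}", element="C", coords=c,
                              residue_name="BNZ"))
        for k in range(6):
            r = BENZENE_CC + BENZENE_CH
            h = np.array([r * np.cos(ang[k]), r * np.sin(ang[k]), 0.0])
            atoms.append(Atom(serial=k + 7, name=f"H{k+1}", element="H", coords=h,
                              residue_name="BNZ"))
    elif kind == "methane":
        atoms.append(Atom(serial=1, name="C1", element="C", coords=np.zeros(3),
                          residue_name="MTH"))
        for k, d in enumerate(_methane_h_directions()):
            atoms.append(Atom(serial=k + 2, name=f"H{k+1}", element="H",
                              coords=METHANE_CH * d, residue_name="MTH"))
    else:
        raise ValueError(f"unknown monomer kind {kind!r}")
    s = Structure(atoms=atoms, bonds=infer_bonds(atoms), source_format="internal")
    return assign_atom_types(s)


def _methane_h_directions() -> list[np.ndarray]:
    """Vertex-down unit C-H directions: H1 along -z, H2-H4 up."""
    a = np.deg2rad(180.0 - TETRA)
    out = [np.array([0.0, 0.0, -1.0])]
    for phi in (0.0, 120.0, 240.0):
        p = np.deg2rad(phi)
        out.append(np.array([np.sin(a) * np.cos(p), np.sin(a) * np.sin(p), np.cos(a)]))
    return out


# ---------------------------------------------------------------------------
# Dimers
# ---------------------------------------------------------------------------

def _orientation_matrix(kind: str, azimuth_deg: float) -> np.ndarray:
    if kind == "vertex":
        rot = Rotation.identity()
    elif kind == "face":
        rot = Rotation.from_euler("x", 180.0, degrees=True)
    elif kind == "edge":
        rot = Rotation.from_euler("y", TETRA / 2.0, degrees=True)
    else:
        raise ValueError(kind)
    return (Rotation.from_euler("z", azimuth_deg, degrees=True) * rot).as_matrix()


def _offset_direction(direction: str) -> np.ndarray:
    """Unit in-plane vector: toward ring carbon C1, or toward the C1-C2 bond
    midpoint."""
    if direction == "toward-ring-carbon":
        return np.array([1.0, 0.0, 0.0])
    mid = np.array([np.cos(0.0) + np.cos(np.pi / 3), np.sin(0.0) + np.sin(np.pi / 3), 0.0])
    return mid / np.linalg.norm(mid)


def build_dimer(spec: DimerSpec) -> tuple[Structure, Structure]:
    """(benzene, methane) structures for a dimer spec.

    The benzene lies in the xy plane centered at the origin; the methane
    carbon sits at ``r_v`` along +z, displaced by ``r_h`` along the chosen
    in-plane direction, in the orientation of the geometry label.
    """
    benzene = build_monomer("benzene")
    methane = build_monomer("methane")
    kind, az = GEOMETRY_ORIENTATIONS[spec.geometry]
    m = _orientation_matrix(kind, az)
    shift = np.array([0.0, 0.0, spec.r_v]) + spec.r_h * _offset_direction(spec.offset_direction)
    for a in methane.atoms:
        a.coords = m @ a.coords + shift
    return benzene, methane


def scan_curve(base: DimerSpec, axis: str, scorer) -> EnergyCurve:
    """Scan the vertical distance or the horizontal offset of a dimer.

    ``scorer(receptor, ligand) -> float`` is evaluated at each grid point;
    the vertical grid is 3.0-4.2 A in 0.1 A steps then 4.4-6.0 A in 0.2 A
    steps, the horizontal grid 0.1 A steps to 1.4 A (ring carbon) or 1.2 A
    (bond midpoint).
    """
    if axis == "vertical":
        grid = VERTICAL_GRID
        specs = [DimerSpec(base.geometry, float(v), base.r_h, base.offset_direction)
                 for v in grid]
    elif axis == "horizontal":
        grid = horizontal_grid(base.offset_direction)
        specs = [DimerSpec(base.geometry, base.r_v, float(v), base.offset_direction)
                 for v in grid]
    else:
        raise ValueError(f"unknown scan axis {axis!r}")
    energies = []
    for sp in specs:
        benzene, methane = build_dimer(sp)
        energies.append(float(scorer(benzene, methane)))
    return EnergyCurve(
        abscissa=grid,
        energies=np.array(energies),
        meta={"geometry": base.geometry, "axis": axis, "r_v": base.r_v,
              "r_h": base.r_h, "offset_direction": base.offset_direction},
    )


def find_minimum(curve: EnergyCurve) -> tuple[float, float] | None:
    """Location and value of the curve minimum, refined by a parabola through
    the three bracketing points.  Returns ``None`` (no-minimum flag) when the
    curve is monotone or flat; ties break to the smallest abscissa."""
    y = curve.energies
    x = curve.abscissa
    i = int(np.argmin(y))  # argmin takes the first (smallest-abscissa) tie
    if i == 0 or i == len(y) - 1 or np.allclose(y, y[0]):
        return None
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    c = (x1 * x2 * (x1 - x2) * y0 + x2 * x0 * (x2 - x0) * y1 + x0 * x1 * (x0 - x1) * y2) / denom
    if a <= 0:
        return float(x1), float(y1)
    xm = -b / (2 * a)
    return float(xm), float(a * xm ** 2 + b * xm + c)


# ---------------------------------------------------------------------------
# Synthetic binding sites
# ---------------------------------------------------------------------------

def make_synthetic_site(
    n_contacts: int,
    descriptor_targets: dict | None = None,
    seed: int = 0,
) -> tuple[Structure, Structure, list[dict]]:
    """Receptor/ligand pair realizing ``n_contacts`` CH-pi contacts with
    sampled descriptor values, plus the ground-truth contact list.

    The receptor is a chain of phenylalanine-like fragments (benzene side
    chain on a CB stub); the ligand carries one methane per contact, posed so
    the ring-facing hydrogen sits exactly at the sampled H-centroid distance
    ``R`` on the ring axis with the C-H bond tilted by the sampled
    ``theta2``.  Sites are spaced 25 A apart so contacts cannot mix.

    ``descriptor_targets`` maps descriptor names to either a fixed value or a
    ``(mean, sd)`` tuple; recognized keys: ``R`` (default (3.0, 0.2), clipped
    to <= 3.4) and ``theta2`` (default (20, 10) deg, clipped to [0, 30] so the
    sibling methane hydrogens stay outside the detection cutoff).
    """
    rng = np.random.default_rng(seed)
    targets = dict(descriptor_targets or {})

    def sample(key, default_mean, default_sd, lo, hi):
        t = targets.get(key, (default_mean, default_sd))
        if np.isscalar(t):
            return float(np.clip(t, lo, hi))
        return float(np.clip(rng.normal(t[0], t[1]), lo, hi))

    rec_atoms: list[Atom] = []
    lig_atoms: list[Atom] = []
    expected: list[dict] = []
    serial_r = serial_l = 0
    names6 = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]

    for k in range(n_contacts):
        origin = np.array([25.0 * k, 0.0, 0.0])
        ang = np.deg2rad(np.arange(6) * 60.0)
        ring = [origin + np.array([BENZENE_CC * np.cos(a), BENZENE_CC * np.sin(a), 0.0])
                for a in ang]
        for name, c in zip(names6, ring):
            serial_r += 1
            rec_atoms.append(Atom(serial=serial_r, name=name, element="C", coords=c,
                                  residue_name="PHE", residue_id=k + 1, chain_id="A",
                                  b_factor=10.0))
        serial_r += 1
        cb = origin + np.array([BENZENE_CC + 1.5, 0.0, -0.4])
        rec_atoms.append(Atom(serial=serial_r, name="CB", element="C", coords=cb,
                              residue_name="PHE", residue_id=k + 1, chain_id="A",
                              b_factor=10.0))

        r = sample("R", 3.0, 0.2, 2.4, 3.4)
        t2 = sample("theta2", 20.0, 10.0, 0.0, 30.0)
        phi = rng.uniform(0, 2 * np.pi)
        h = origin + np.array([0.0, 0.0, r])
        tilt = np.deg2rad(t2)
        u = np.array([np.sin(tilt) * np.cos(phi), np.sin(tilt) * np.sin(phi), np.cos(tilt)])
        c = h + METHANE_CH * u  # C-H vector (c -> h) = -u, tilted t2 from -z
        serial_l += 1
        lig_atoms.append(Atom(serial=serial_l, name=f"C{k+1}", element="C", coords=c,
                              residue_name="LIG", residue_id=1, chain_id="L"))
        serial_l += 1
        lig_atoms.append(Atom(serial=serial_l, name=f"H{k+1}a", element="H", coords=h,
                              residue_name="LIG", residue_id=1, chain_id="L"))
        # complete the methane so it is a real CH4 (not a bare C-H)
        for m, d in enumerate(_complete_tetrahedron(-u)):
            serial_l += 1
            lig_atoms.append(Atom(serial=serial_l, name=f"H{k+1}{'bcd'[m]}", element="H",
                                  coords=c + METHANE_CH * d, residue_name="LIG",
                                  residue_id=1, chain_id="L"))
        expected.append({"R": r, "theta2": t2, "ring_residue": k + 1})

    from .hydrogens import add_aliphatic_hydrogens

    receptor = Structure(atoms=rec_atoms, bonds=infer_bonds(rec_atoms),
                         source_format="internal")
    receptor = assign_atom_types(add_aliphatic_hydrogens(receptor))
    ligand = assign_atom_types(
        Structure(atoms=lig_atoms, bonds=infer_bonds(lig_atoms), source_format="internal")
    )
    return receptor, ligand, expected


def _complete_tetrahedron(v: np.ndarray) -> list[np.ndarray]:
    """Three unit vectors completing ``v`` to a tetrahedral set."""
    v = v / np.linalg.norm(v)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, v)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    cos_t = np.cos(np.deg2rad(TETRA))
    sin_t = np.sin(np.deg2rad(TETRA))
    out = []
    for phi in (0.0, 120.0, 240.0):
        p = np.deg2rad(phi)
        out.append(cos_t * v + sin_t * (np.cos(p) * e1 + np.sin(p) * e2))
    return out
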