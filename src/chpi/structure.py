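"""Molecular structure model and PDB/PDBQT input-output.

The in-memory model is deliberately small: an ordered list of :class:`Atom`
records plus an undirected bond list.  PDB files are parsed and written
through :mod:`gemmi`; the PDBQT dialect (AutoDock-style columns, with
ROOT/BRANCH/TORSDOF torsion-tree records) has no reader in the scientific
Python stack and is handled by a fixed-column parser here.  Torsion-tree
records are retained as annotations only -- they play no role in scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Structure",
    "FormatError",
    "ElementError",
    "read_structure",
    "write_structure",
    "infer_bonds",
]

# Docking atom classes used by the scoring layer.
ALIPHATIC_C = "aliphatic-carbon"
AROMATIC_C = "aromatic-carbon"
RING_N = "ring-nitrogen"
POLAR = "polar"
HYDROGEN = "hydrogen"
OTHER = "other"

_PERIODIC = {
    "H", "HE", "LI", "BE", "B", "C", "N", "O", "F", "NE", "NA", "MG", "AL",
    "SI", "P", "S", "CL", "AR", "K", "CA", "SC", "TI", "V", "CR", "MN", "FE",
    "CO", "NI", "CU", "ZN", "GA", "GE", "AS", "SE", "BR", "KR", "RB", "SR",
    "Y", "ZR", "MO", "RU", "RH", "PD", "AG", "CD", "IN", "SN", "SB", "TE",
    "I", "XE", "CS", "BA", "W", "RE", "OS", "IR", "PT", "AU", "HG", "TL",
    "PB", "BI",
}

# PDBQT AutoDock types -> element.  AutoDock distinguishes aromatic carbon
# (A) and hydrogen-bonding variants (OA, NA, SA, HD); map them back.
_AUTODOCK_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "S": "S", "SA": "S", "H": "H", "HD": "H", "HS": "H", "P": "P",
    "F": "F", "CL": "CL", "BR": "BR", "I": "I", "MG": "MG", "MN": "MN",
    "ZN": "ZN", "CA": "CA", "FE": "FE",
}


class FormatError(ValueError):
    """A structure file could not be parsed under the requested dialect."""


class ElementError(ValueError):
    """An atom record carries an unknown element symbol."""


@dataclass
class Atom:
    """One atom with the crystallographic fields the contact filters need."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    residue_name: str = "UNK"
    residue_id: int = 1
    chain_id: str = "A"
    docking_type: str = OTHER
    autodock_type: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} not in [0, 1]")
        if self.b_factor < 0.0:
            raise ValueError(f"atom {self.serial}: negative B-factor")
        el = self.element.upper()
        if el not in _PERIODIC:
            raise ElementError(f"atom {self.serial}: unknown element {self.element!r}")
        self.element = el if len(el) > 1 else self.element.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def partial_occupancy(self) -> bool:
        return self.occupancy < 1.0


@dataclass
class Structure:
    """An ordered atom collection with an undirected bond list."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    source_format: str = "internal"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms]) if self.atoms else np.empty((0, 3))

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def neighbor_table(self) -> list[list[int]]:
        table: list[list[int]] = [[] for _ in self.atoms]
        for a, b in self.bonds:
            table[a].append(b)
            table[b].append(a)
        return table

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]

    def copy(self) -> "Structure":
        return Structure(
            atoms=[replace(a, coords=a.coords.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            source_format=self.source_format,
            annotations=dict(self.annotations),
        )

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Group atom indices by (chain, residue id, residue name)."""
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            groups.setdefault((a.chain_id, a.residue_id, a.residue_name), []).append(i)
        return groups


# ---------------------------------------------------------------------------
# Bond inference
# ---------------------------------------------------------------------------

def infer_bonds(atoms: Sequence[Atom]) -> list[tuple[int, int]]:
    """Distance-criterion bonds: 1.9 A cutoff, 2.2 A when sulfur is involved,
    1.2 A when either atom is hydrogen (an H bonds to its nearest partner only).
    """
    if not atoms:
        return []
    xyz = np.array([a.coords for a in atoms])
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=2.2, output_type="ndarray")
    bonds: list[tuple[int, int]] = []
    h_partner: dict[int, tuple[int, float]] = {}
    for i, j in pairs:
        i, j = int(i), int(j)
        ai, aj = atoms[i], atoms[j]
        d = float(np.linalg.norm(ai.coords - aj.coords))
        if ai.is_hydrogen and aj.is_hydrogen:
            continue
        if ai.is_hydrogen or aj.is_hydrogen:
            if d > 1.25:
                continue
            h, x = (i, j) if ai.is_hydrogen else (j, i)
            best = h_partner.get(h)
            if best is None or d < best[1]:
                h_partner[h] = (x, d)
            continue
        cutoff = 2.2 if "S" in (ai.element, aj.element) else 1.9
        if d <= cutoff:
            bonds.append((i, j))
    for h, (x, _) in h_partner.items():
        bonds.append((min(h, x), max(h, x)))
    return sorted(set(bonds))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or PDBQT file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read.
    fmt:
        ``"pdb"``, ``"pdbqt"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"
    fmt = fmt.lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "pdbqt":
        return _read_pdbqt(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_pdb(path: Path) -> Structure:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message
        raise FormatError(f"{path}: {exc}") from exc
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                for at in res:
                    el = at.element.name.upper()
                    if el in ("", "X"):
                        raise ElementError(
                            f"{path}: atom {at.serial} {at.name!r} has no recognizable element"
                        )
                    atoms.append(
                        Atom(
                            serial=at.serial,
                            name=at.name,
                            element=el,
                            coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            occupancy=min(1.0, at.occ),
                            b_factor=max(0.0, at.b_iso),
                            residue_name=res.name,
                            residue_id=res.seqid.num,
                            chain_id=chain.name,
                        )
                    )
        break  # first model only
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records parsed")
    return Structure(atoms=atoms, bonds=infer_bonds(atoms), source_format="PDB")


def _read_pdbqt(path: Path) -> Structure:
    atoms: list[Atom] = []
    tree_records: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ROOT", "ENDROO", "BRANCH", "ENDBRA", "TORSDO"):
            tree_records.append(line.strip())
            continue
        if rec not in ("ATOM", "HETATM"):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            resname = line[17:20].strip() or "UNK"
            chain = line[21:22].strip() or "A"
            resid = int(line[22:26]) if line[22:26].strip() else 1
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            occ = float(line[54:60]) if line[54:60].strip() else 1.0
            b = float(line[60:66]) if line[60:66].strip() else 0.0
            adtype = line[77:79].strip()
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed PDBQT record: {line!r}") from exc
        element = _AUTODOCK_ELEMENT.get(adtype.upper())
        if element is None:
            raise ElementError(f"{path}:{lineno}: unknown AutoDock type {adtype!r}")
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                coords=np.array([x, y, z]),
                occupancy=min(1.0, occ),
                b_factor=max(0.0, b),
                residue_name=resname,
                residue_id=resid,
                chain_id=chain,
                autodock_type=adtype.upper(),
            )
        )
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records parsed")
    return Structure(atoms=atoms, bonds=infer_bonds(atoms), source_format="PDBQT",
                     annotations={"torsion_tree": tree_records})


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_structure(s: Structure, path: str | Path, fmt: str = "auto") -> None:
    """Write ``s`` as PDB or PDBQT (coordinates at the format's 3-decimal
    precision)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "pdbqt" if path.suffix.lower() == ".pdbqt" else "pdb"
    lines = []
    for a in s.atoms:
        if fmt == "pdb":
            tail = f"          {a.element:>2s}"
        else:
            ad = a.autodock_type or _default_autodock_type(a)
            tail = f"    {0.0:6.3f} {ad:<2s}"  # charge column, then AutoDock type
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:>5d} {name:<4s} {a.residue_name:<3s} {a.chain_id:1s}"
            f"{a.residue_id:>4d}    {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}{tail}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _default_autodock_type(a: Atom) -> str:
    if a.docking_type == AROMATIC_C:
        return "A"
    if a.element == "O":
        return "OA"
    if a.element == "N":
        return "NA"
    return a.element[:2].capitalize() if len(a.element) > 1 else a.element
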