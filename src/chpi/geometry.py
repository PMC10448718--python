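"""Geometric descriptors of a single C-H / aromatic-ring contact.

Descriptors (all rigid-motion invariant):

``R``
    aliphatic H to ring-centroid distance.
``theta``
    C-H-centroid angle at the hydrogen (180 deg = H points at the centroid).
``omega``
    dihedral between the ring plane and the plane through the H and its two
    nearest ring carbons, folded to [0, 90] deg.
``theta1``
    angle between the aliphatic-carbon-to-centroid vector and the ring
    normal (0 deg = carbon on the ring axis), folded to [0, 90].
``theta2``
    tilt angle between the C-H bond vector and the ring normal, folded to
    [0, 90] (the sign of the normal is not observable).
``r_h`` / ``r_v``
    horizontal (in-plane) and vertical (along-normal) components of the
    carbon-centroid offset; ``r_h_h`` / ``r_v_h`` the same for the hydrogen,
    so that ``R^2 = r_h_h^2 + r_v_h^2``.
``c_centroid``
    aliphatic-carbon-to-centroid distance (>= r_v by construction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rings import AromaticRing
from .structure import Structure

__all__ = ["ChPiGeometry", "chpi_geometry"]


@dataclass(frozen=True)
class ChPiGeometry:
    r: float
    theta: float
    omega: float
    theta1: float
    theta2: float
    r_h: float
    r_v: float
    r_h_h: float
    r_v_h: float
    c_centroid: float

    def as_dict(self) -> dict[str, float]:
        return {
            "R": self.r, "theta": self.theta, "omega": self.omega,
            "theta1": self.theta1, "theta2": self.theta2,
            "R_H": self.r_h, "R_V": self.r_v,
            "R_H_H": self.r_h_h, "R_V_H": self.r_v_h,
            "C_centroid": self.c_centroid,
        }


def _angle(u: np.ndarray, v: np.ndarray) -> float:
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _folded_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between lines (sign of either vector immaterial), in [0, 90]."""
    a = _angle(u, v)
    return min(a, 180.0 - a)


def chpi_geometry(
    c_xyz: np.ndarray,
    h_xyz: np.ndarray,
    ring: AromaticRing,
    structure: Structure | None = None,
    ring_carbon_coords: np.ndarray | None = None,
) -> ChPiGeometry:
    """All descriptors for one aliphatic C-H against one aromatic ring.

    ``ring_carbon_coords`` (or ``structure``, from which they are looked up)
    supplies the ring-atom coordinates needed for the omega dihedral.
    """
    c_xyz = np.asarray(c_xyz, float)
    h_xyz = np.asarray(h_xyz, float)
    n = ring.normal
    cen = ring.centroid

    hc = h_xyz - cen
    cc = c_xyz - cen
    r = float(np.linalg.norm(hc))
    c_centroid = float(np.linalg.norm(cc))
    theta = _angle(c_xyz - h_xyz, cen - h_xyz)
    theta1 = _folded_angle(cc, n)
    theta2 = _folded_angle(h_xyz - c_xyz, n)
    r_v = abs(float(np.dot(cc, n)))
    r_h = float(np.linalg.norm(cc - np.dot(cc, n) * n))
    r_v_h = abs(float(np.dot(hc, n)))
    r_h_h = float(np.linalg.norm(hc - np.dot(hc, n) * n))

    if ring_carbon_coords is None:
        if structure is None:
            raise ValueError("need structure or ring_carbon_coords for omega")
        ring_carbon_coords = np.array(
            [structure.atoms[i].coords for i in ring.atom_indices]
        )
    # nearest *adjacent* ring-atom pair (ring coords are in path order);
    # restricting to edges keeps the choice stable for on-axis contacts
    d = np.linalg.norm(ring_carbon_coords - h_xyz, axis=1)
    m = len(ring_carbon_coords)
    edge = min(range(m), key=lambda i: d[i] + d[(i + 1) % m])
    p1, p2 = ring_carbon_coords[edge], ring_carbon_coords[(edge + 1) % m]
    plane_n = np.cross(p2 - p1, h_xyz - p1)
    norm = np.linalg.norm(plane_n)
    if norm < 1e-10:
        raise ValueError("degenerate H/ring-carbon plane for omega")
    omega = _folded_angle(plane_n / norm, n)

    return ChPiGeometry(
        r=r, theta=theta, omega=omega, theta1=theta1, theta2=theta2,
        r_h=r_h, r_v=r_v, r_h_h=r_h_h, r_v_h=r_v_h, c_centroid=c_centroid,
    )
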