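import numpy as np
import pytest

from chpi import (
    Atom,
    Structure,
    assign_atom_types,
    build_monomer,
    infer_bonds,
)


@pytest.fixture
def benzene():
    return build_monomer("benzene")


@pytest.fixture
def methane():
    return build_monomer("methane")


@pytest.fixture
def rng():
    return np.random.default_rng(20230726)


def make_structure(records, bonds=None, typed=True):
    """records: (name, element, xyz[, kwargs]) tuples."""
    atoms = []
    for k, rec in enumerate(records):
        name, element, xyz = rec[:3]
        kw = rec[3] if len(rec) > 3 else {}
        atoms.append(Atom(serial=k + 1, name=name, element=element,
                          coords=np.asarray(xyz, float), **kw))
    s = Structure(atoms=atoms, bonds=bonds if bonds is not None else infer_bonds(atoms),
                  source_format="internal")
    return assign_atom_types(s) if typed else s


def random_rigid_motion(rng):
    """A uniformly random rotation matrix and a translation."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    rot = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
    t = rng.uniform(-20, 20, size=3)
    return rot, t


def apply_rigid(s, rot, t):
    out = s.copy()
    for a in out.atoms:
        a.coords = rot @ a.coords + t
    return out
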