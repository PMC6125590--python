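import numpy as np
import pytest

from tailbind.structure import Atom, Structure


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_point_structure(coords, chain="A", name="CA", element="C",
                         residue_ids=None, groups=None):
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    rid = residue_ids if residue_ids is not None else range(1, n + 1)
    atoms = [
        Atom(i + 1, name, element, "GLY", int(r), chain, coords[i])
        for i, r in zip(range(n), rid)
    ]
    return Structure.from_atoms(atoms, groups=groups or {})


@pytest.fixture
def two_group_structure():
    """Five tail atoms and five ligand atoms on well-separated lines."""
    tail = np.column_stack([np.arange(5) * 10.0, np.full(5, 30.0),
                            np.zeros(5)])
    lig = np.column_stack([np.arange(5) * 10.0, np.zeros(5), np.zeros(5)])
    atoms = []
    for i, p in enumerate(tail):
        atoms.append(Atom(i + 1, "CA", "C", "GLY", i + 1, "T", p))
    for i, p in enumerate(lig):
        atoms.append(Atom(i + 6, "CA", "C", "GLY", i + 1, "M", p))
    return Structure.from_atoms(atoms, groups={
        "tail": np.arange(5), "ligand": np.arange(5, 10)})
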