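"""Structure and ensemble I/O: PDB via biotite, PQR via MDAnalysis.

PDB files carry identities and coordinates (multi-model files carry
ensembles); PQR files carry per-atom charges and radii in the standard
whitespace-delimited dialect.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np

from .ensemble import TrajectoryEnsemble
from .errors import ParseError
from .structure import Structure

__all__ = [
    "read_structure", "write_structure",
    "read_ensemble", "write_ensemble",
    "read_pqr", "write_pqr",
]


def _element_from_name(name: str) -> str:
    stripped = "".join(c for c in str(name) if c.isalpha())
    return stripped[:1].upper() if stripped else "X"


def _to_structure(arr, serials=None) -> Structure:
    n = arr.array_length()
    elements = np.array(
        [e if e else _element_from_name(nm)
         for e, nm in zip(arr.element, arr.atom_name)], dtype=object)
    return Structure(
        serial=np.asarray(serials) if serials is not None
        else np.arange(1, n + 1),
        name=np.array(arr.atom_name, dtype=object),
        element=elements,
        residue_name=np.array(arr.res_name, dtype=object),
        residue_index=np.array(arr.res_id, dtype=int),
        chain_id=np.array(arr.chain_id, dtype=object),
        coords=np.asarray(arr.coord, dtype=float),
    )


def _to_atom_array(structure: Structure, coords=None):
    import biotite.structure as bst

    n = structure.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(
        structure.coords if coords is None else coords, dtype=np.float32)
    arr.chain_id = structure.chain_id.astype("U4")
    arr.res_id = structure.residue_index.astype(int)
    arr.res_name = structure.residue_name.astype("U5")
    arr.atom_name = structure.name.astype("U6")
    arr.element = structure.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def read_structure(pdb_source, model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    ``pdb_source`` may be a path or a file-like object with PDB text.
    Malformed ATOM records raise :class:`ParseError`.
    """
    import biotite.structure.io.pdb as pdb

    try:
        f = pdb.PDBFile.read(pdb_source)
        arr = f.get_structure(model=model, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises several parse-time types
        raise ParseError(f"could not parse PDB source: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError("PDB source contains no ATOM records")
    return _to_structure(arr, serials=arr.atom_id)


def write_structure(structure: Structure, path) -> None:
    """Write a single-model PDB file."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(_to_atom_array(structure))
    f.write(str(path))


def read_ensemble(pdb_sources, structure: Structure | None = None
                  ) -> TrajectoryEnsemble:
    """Read replicate multi-model PDB files into a trajectory ensemble.

    ``pdb_sources`` is one source or a list (one per replicate); every model
    becomes one frame. Topology is taken from the first model unless given.
    """
    import biotite.structure.io.pdb as pdb

    if isinstance(pdb_sources, (str, Path, _io.IOBase)):
        pdb_sources = [pdb_sources]
    replicates = []
    for src in pdb_sources:
        try:
            f = pdb.PDBFile.read(src)
            stack = f.get_structure(model=None)
        except Exception as exc:
            raise ParseError(f"could not parse PDB source: {exc}") from exc
        if structure is None:
            structure = _to_structure(stack[0])
        replicates.append(np.asarray(stack.coord, dtype=float))
    return TrajectoryEnsemble(structure=structure, replicates=replicates)


def write_ensemble(ensemble: TrajectoryEnsemble, paths) -> None:
    """Write each replicate as a multi-model PDB file."""
    import biotite.structure as bst
    import biotite.structure.io.pdb as pdb

    if isinstance(paths, (str, Path)):
        paths = [paths]
    if len(paths) != ensemble.n_replicates:
        raise ValueError("need one output path per replicate")
    template = _to_atom_array(ensemble.structure)
    for path, coords in zip(paths, ensemble.replicates):
        stack = bst.from_template(template, coords.astype(np.float32))
        f = pdb.PDBFile()
        f.set_structure(stack)
        f.write(str(path))


def read_pqr(path) -> Structure:
    """Read a PQR file (charges + radii) via MDAnalysis."""
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(path))
    except Exception as exc:
        raise ParseError(f"could not parse PQR source: {exc}") from exc
    atoms = u.atoms
    n = len(atoms)
    if n == 0:
        raise ParseError("PQR source contains no atoms")
    try:
        elements = np.array([str(e).capitalize() for e in atoms.elements],
                            dtype=object)
    except Exception:
        elements = np.array([_element_from_name(nm) for nm in atoms.names],
                            dtype=object)
    try:
        chains = np.array([str(c) for c in atoms.chainIDs], dtype=object)
    except Exception:
        chains = np.array([str(s) for s in atoms.segids], dtype=object)
    return Structure(
        serial=np.asarray(atoms.ids, dtype=int),
        name=np.array([str(x) for x in atoms.names], dtype=object),
        element=elements,
        residue_name=np.array([str(x) for x in atoms.resnames], dtype=object),
        residue_index=np.asarray(atoms.resids, dtype=int),
        chain_id=chains,
        coords=np.asarray(atoms.positions, dtype=float),
        charge=np.asarray(atoms.charges, dtype=float),
        radius=np.asarray(atoms.radii, dtype=float),
    )


def write_pqr(structure: Structure, path) -> None:
    """Write the whitespace-delimited standard PQR dialect.

    Requires charges and radii on every atom.
    """
    if np.isnan(structure.charge).any() or np.isnan(structure.radius).any():
        raise ValueError("write_pqr needs charges and radii on every atom")
    with open(path, "w") as fh:
        fh.write("REMARK   1 PQR file written by tailbind\n")
        for i in range(structure.n_atoms):
            x, y, z = structure.coords[i]
            fh.write(
                "ATOM  {serial:>5d} {name:<4s} {res:<4s} {resid:>5d}    "
                "{x:10.4f} {y:10.4f} {z:10.4f} {q:8.4f} {r:7.4f}\n".format(
                    serial=int(structure.serial[i]),
                    name=str(structure.name[i]),
                    res=str(structure.residue_name[i]),
                    resid=int(structure.residue_index[i]),
                    x=x, y=y, z=z,
                    q=structure.charge[i], r=structure.radius[i],
                )
            )
        fh.write("END\n")
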