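"""Structure container, in-silico tail construction, charge models, rigid offsets.

The receptor/ligand systems handled here are small enough that a plain
array-of-records container is the right tool: coordinates, identities and
optional per-atom charges/radii live in parallel numpy arrays, and named
atom groups (e.g. ``"MTBD"``, ``"EhookB"``) are index arrays into them.

Tails (the acidic C-terminal E-hooks of tubulin) are built in an idealised
extended backbone conformation from their one-letter sequence; the paper-scale
alternative (homology modelling) only provides starting coordinates that are
re-sampled into ensembles afterwards, so ideal geometry is sufficient here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import IncompleteStructureError, InvalidSelectionError

__all__ = [
    "Atom",
    "Structure",
    "OffsetLadder",
    "build_tail",
    "assign_charges",
    "formal_residue_charges",
    "offset_ladder_structures",
    "offset_ligand",
    "ALPHA_TAIL_SEQUENCE",
    "BETA_TAIL_SEQUENCE",
]

# Bos taurus tubulin C-terminal tail (E-hook) sequences.
ALPHA_TAIL_SEQUENCE = "VGVDSVEGEGEEEGEEY"
BETA_TAIL_SEQUENCE = "DATADEQGEFEEEGEEDEA"

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Bondi-style van der Waals radii by element (Å); used by the formal model
# when no PQR radii are supplied.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    """One atom record; ``charge``/``radius`` are optional annotations."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    charge: float | None = None
    radius: float | None = None

    def __post_init__(self):
        if not self.element:
            raise ValueError("Atom.element must be non-empty")
        if self.radius is not None and self.radius < 0:
            raise ValueError("Atom.radius must be >= 0")
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(3)
        )


@dataclass
class Structure:
    """Ordered collection of atoms with named index groups.

    All identity columns are parallel arrays of length ``n_atoms``; ``charge``
    and ``radius`` hold NaN where unassigned.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_index: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray
    charge: np.ndarray | None = None
    radius: np.ndarray | None = None
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for col in ("serial", "name", "element", "residue_name",
                    "residue_index", "chain_id"):
            arr = np.asarray(getattr(self, col))
            if len(arr) != n:
                raise ValueError(f"column {col!r} has length {len(arr)} != {n}")
            setattr(self, col, arr)
        if self.charge is None:
            self.charge = np.full(n, np.nan)
        if self.radius is None:
            self.radius = np.full(n, np.nan)
        self.charge = np.asarray(self.charge, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        for gname, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise InvalidSelectionError(
                    f"group {gname!r} has indices outside [0, {n})"
                )
            self.groups[gname] = idx

    # -- basic introspection ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return self.n_atoms

    def atom(self, i: int) -> Atom:
        ch = self.charge[i]
        rad = self.radius[i]
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            residue_name=str(self.residue_name[i]),
            residue_index=int(self.residue_index[i]),
            chain_id=str(self.chain_id[i]),
            position=self.coords[i],
            charge=None if np.isnan(ch) else float(ch),
            radius=None if np.isnan(rad) else float(rad),
        )

    @property
    def heavy_mask(self) -> np.ndarray:
        """True for every atom that is not hydrogen (or deuterium)."""
        elems = np.char.upper(self.element.astype(str))
        return ~np.isin(elems, ("H", "D"))

    def group(self, name_or_indices) -> np.ndarray:
        if isinstance(name_or_indices, str):
            try:
                return self.groups[name_or_indices]
            except KeyError:
                raise InvalidSelectionError(
                    f"no group named {name_or_indices!r}"
                ) from None
        return np.asarray(name_or_indices, dtype=int)

    def select(self, chain: str | None = None,
               residues: tuple[int, int] | None = None) -> np.ndarray:
        """Indices of atoms by chain id and inclusive residue-index range."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_id.astype(str) == chain
        if residues is not None:
            lo, hi = residues
            mask &= (self.residue_index >= lo) & (self.residue_index <= hi)
        return np.flatnonzero(mask)

    def chain_groups(self) -> dict[str, np.ndarray]:
        return {
            str(c): np.flatnonzero(self.chain_id.astype(str) == str(c))
            for c in np.unique(self.chain_id.astype(str))
        }

    def residue_ids(self, indices) -> list[tuple[str, int, str]]:
        """Ordered unique (chain, residue_index, residue_name) over a selection."""
        idx = self.group(indices)
        seen, out = set(), []
        for i in idx:
            key = (str(self.chain_id[i]), int(self.residue_index[i]))
            if key not in seen:
                seen.add(key)
                out.append((*key, str(self.residue_name[i])))
        return out

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_atoms(cls, atoms: list[Atom],
                   groups: dict[str, np.ndarray] | None = None) -> "Structure":
        return cls(
            serial=np.array([a.serial for a in atoms], dtype=int),
            name=np.array([a.name for a in atoms], dtype=object),
            element=np.array([a.element for a in atoms], dtype=object),
            residue_name=np.array([a.residue_name for a in atoms], dtype=object),
            residue_index=np.array([a.residue_index for a in atoms], dtype=int),
            chain_id=np.array([a.chain_id for a in atoms], dtype=object),
            coords=np.array([a.position for a in atoms], dtype=float).reshape(-1, 3),
            charge=np.array(
                [np.nan if a.charge is None else a.charge for a in atoms]),
            radius=np.array(
                [np.nan if a.radius is None else a.radius for a in atoms]),
            groups=groups or {},
        )

    def copy(self) -> "Structure":
        return Structure(
            serial=self.serial.copy(), name=self.name.copy(),
            element=self.element.copy(), residue_name=self.residue_name.copy(),
            residue_index=self.residue_index.copy(),
            chain_id=self.chain_id.copy(), coords=self.coords.copy(),
            charge=self.charge.copy(), radius=self.radius.copy(),
            groups={k: v.copy() for k, v in self.groups.items()},
        )

    def concat(self, other: "Structure") -> "Structure":
        """Append ``other``'s atoms; group indices of ``other`` are shifted."""
        off = self.n_atoms
        groups = {k: v.copy() for k, v in self.groups.items()}
        for k, v in other.groups.items():
            groups[k] = np.concatenate([groups[k], v + off]) if k in groups \
                else v + off
        return Structure(
            serial=np.concatenate([self.serial, other.serial]),
            name=np.concatenate([self.name, other.name]),
            element=np.concatenate([self.element, other.element]),
            residue_name=np.concatenate([self.residue_name, other.residue_name]),
            residue_index=np.concatenate([self.residue_index,
                                          other.residue_index]),
            chain_id=np.concatenate([self.chain_id, other.chain_id]),
            coords=np.vstack([self.coords, other.coords]),
            charge=np.concatenate([self.charge, other.charge]),
            radius=np.concatenate([self.radius, other.radius]),
            groups=groups,
        )


@dataclass(frozen=True)
class OffsetLadder:
    """Perpendicular displacement axis plus a strictly increasing distance list.

    The default axis is +y, the direction normal to the microtubule surface in
    the complex's frame; distances are in Å.
    """

    axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    distances: tuple[float, ...] = (5.0, 15.0, 25.0, 35.0, 45.0, 55.0)

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
            raise ValueError("OffsetLadder.axis must have unit norm")
        object.__setattr__(self, "axis", axis)
        d = tuple(float(x) for x in self.distances)
        if any(x < 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError(
                "OffsetLadder.distances must be non-negative, strictly increasing")
        object.__setattr__(self, "distances", d)


# ---------------------------------------------------------------------------
# tail construction (ideal internal coordinates, NeRF placement)
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """Natural-extension placement of atom d from reference frame a-b-c."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # a-b-c collinear: any perpendicular works as the torsion reference
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, bc)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        n = np.cross(probe, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(angle),
        np.sin(angle) * np.cos(torsion),
        np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# ideal backbone internal coordinates (Å, degrees)
_B = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "CA-CB": 1.530, "C-C": 1.520, "C-OX": 1.250, "C-NZ": 1.489,
}
_A = {
    "C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2, "CA-C-O": 120.8,
    "N-CA-CB": 110.5, "CHAIN": 114.0, "CARBOXYL": 118.5,
}

# minimal side chains: linear heavy-atom extensions past CB, enough to carry
# formal charges and to perturb for synthetic conformers
_SIDE_CHAIN_EXTENSIONS = {
    "ASP": ["CG", "OD1", "OD2"],
    "GLU": ["CG", "CD", "OE1", "OE2"],
    "LYS": ["CG", "CD", "CE", "NZ"],
    "ARG": ["CG", "CD", "NE", "CZ"],
}

# atom carrying the formal charge of an ionisable side chain (the carboxylate
# centre for Asp/Glu, the basic nitrogen / guanidinium centre for Lys/Arg)
FORMAL_CHARGE_CARRIER = {
    "ASP": ("CG", -1.0),
    "GLU": ("CD", -1.0),
    "LYS": ("NZ", +1.0),
    "ARG": ("CZ", +1.0),
}


def build_tail(
    anchor: np.ndarray | None,
    sequence: str,
    chain_id: str = "T",
    start_residue: int = 1,
    start_serial: int = 1,
    phi: float | np.ndarray = -120.0,
    psi: float | np.ndarray = 120.0,
    group_name: str | None = None,
) -> Structure:
    """Build a peptide fragment in extended backbone geometry.

    Parameters
    ----------
    anchor
        ``(3, 3)`` array holding the N, CA, C coordinates of the residue the
        tail continues from (a C-terminal backbone anchor), or ``None`` to
        start a free chain at the origin.
    sequence
        One-letter amino-acid codes, one residue appended per letter.
    phi, psi
        Backbone dihedrals in degrees; scalars are broadcast, per-residue
        arrays allow conformer generation. Defaults are the ideal extended
        conformation (φ = −120°, ψ = 120°).

    Returns
    -------
    Structure
        The fragment only (anchor atoms are not included). Residue indices
        continue from ``start_residue``; Asp/Glu/Lys/Arg receive minimal
        side chains so charge carriers exist.
    """
    sequence = str(sequence)
    for letter in sequence:
        if letter.upper() not in ONE_TO_THREE:
            raise ValueError(f"unknown residue letter {letter!r}")
    nres = len(sequence)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (nres,))
    psi = np.broadcast_to(np.asarray(psi, dtype=float), (nres,))

    atoms: list[Atom] = []
    serial = start_serial

    def add(name, element, resname, resid, pos):
        nonlocal serial
        atoms.append(Atom(serial, name, element, resname, resid, chain_id,
                          np.asarray(pos, dtype=float)))
        serial += 1

    if anchor is not None:
        prev_n, prev_ca, prev_c = (np.asarray(anchor, dtype=float)
                                   .reshape(3, 3))
    else:
        # synthetic anchor frame so the first residue starts near the origin
        prev_n = np.array([-2.428, 1.175, 0.0])
        prev_ca = np.array([-1.329, 0.223, 0.0])
        prev_c = np.array([0.0, 0.953, 0.0])

    for k, letter in enumerate(sequence):
        resname = ONE_TO_THREE[letter.upper()]
        resid = start_residue + k
        # peptide bond: omega fixed trans (180°)
        n = _place_atom(prev_n, prev_ca, prev_c,
                        _B["C-N"], _A["CA-C-N"], psi[k - 1] if k else 120.0)
        ca = _place_atom(prev_ca, prev_c, n, _B["N-CA"], _A["C-N-CA"], 180.0)
        c = _place_atom(prev_c, n, ca, _B["CA-C"], _A["N-CA-C"], phi[k])
        o = _place_atom(n, ca, c, _B["C-O"], _A["CA-C-O"], psi[k] + 180.0)
        add("N", "N", resname, resid, n)
        add("CA", "C", resname, resid, ca)
        add("C", "C", resname, resid, c)
        add("O", "O", resname, resid, o)
        if resname != "GLY":
            cb = _place_atom(c, n, ca, _B["CA-CB"], _A["N-CA-CB"], 123.0)
            add("CB", "C", resname, resid, cb)
            ext = _SIDE_CHAIN_EXTENSIONS.get(resname, ())
            a3, a2, a1 = n, ca, cb
            for j, aname in enumerate(ext):
                terminal_pair = resname in ("ASP", "GLU") and aname.startswith("O")
                if terminal_pair:
                    torsion = 0.0 if aname.endswith("1") else 180.0
                    pos = _place_atom(a3, a2, a1, _B["C-OX"],
                                      _A["CARBOXYL"], torsion)
                    add(aname, "O", resname, resid, pos)
                    continue  # both carboxylate oxygens hang off the same frame
                element = aname[0]
                bond = _B["C-NZ"] if element == "N" else _B["C-C"]
                pos = _place_atom(a3, a2, a1, bond, _A["CHAIN"], 180.0)
                add(aname, element, resname, resid, pos)
                a3, a2, a1 = a2, a1, pos
        prev_n, prev_ca, prev_c = n, ca, c

    groups = {}
    if group_name is not None:
        groups[group_name] = np.arange(len(atoms))
    return Structure.from_atoms(atoms, groups=groups)


# ---------------------------------------------------------------------------
# charge assignment
# ---------------------------------------------------------------------------

def formal_residue_charges(sequence: str) -> int:
    """Signed formal charge of a sequence under the side-chain-only rule."""
    seq = sequence.upper()
    return sum({"D": -1, "E": -1, "K": +1, "R": +1}.get(x, 0) for x in seq)


def assign_charges(
    structure: Structure,
    model: str = "formal",
    pqr_source=None,
    charge_termini: bool = False,
    selection=None,
) -> Structure:
    """Attach per-atom charges and radii.

    ``model="formal"`` places integer charges on side-chain carrier atoms
    (−1 on the Asp/Glu carboxylate-centre atom, +1 on Lys NZ / Arg CZ) and
    element-based van der Waals radii everywhere; Asp/Glu are always kept
    deprotonated, matching the fixed-ionisation rule for acidic tails at
    pH 7. Termini are uncharged unless ``charge_termini`` is set.

    ``model="pqr"`` copies charges and radii verbatim from a PQR source
    (path or file-like), matched by atom order.
    """
    out = structure.copy()
    if model == "pqr":
        from .io import read_pqr

        if pqr_source is None:
            raise ValueError("model='pqr' requires pqr_source")
        ref = pqr_source if isinstance(pqr_source, Structure) \
            else read_pqr(pqr_source)
        if ref.n_atoms != out.n_atoms:
            raise IncompleteStructureError(
                f"PQR atom count {ref.n_atoms} != structure {out.n_atoms}")
        out.charge = ref.charge.copy()
        out.radius = ref.radius.copy()
        return out
    if model != "formal":
        raise ValueError(f"unknown charge model {model!r}")

    idx = np.arange(out.n_atoms) if selection is None else out.group(selection)
    elems = np.char.upper(out.element.astype(str))
    out.radius[idx] = [VDW_RADII.get(e, DEFAULT_RADIUS) for e in elems[idx]]
    out.charge[idx] = 0.0

    sel = set(idx.tolist())
    for chain, resid, resname in out.residue_ids(idx):
        if resname not in FORMAL_CHARGE_CARRIER:
            continue
        carrier, q = FORMAL_CHARGE_CARRIER[resname]
        res_mask = ((out.chain_id.astype(str) == chain)
                    & (out.residue_index == resid))
        res_idx = [i for i in np.flatnonzero(res_mask) if i in sel]
        names = {str(out.name[i]): i for i in res_idx}
        if carrier not in names:
            raise IncompleteStructureError(
                f"residue {resname} {chain}:{resid} lacks side-chain atom "
                f"{carrier!r} required by the formal charge model")
        out.charge[names[carrier]] = q

    if charge_termini:
        for chain in np.unique(out.chain_id.astype(str)):
            cidx = [i for i in np.flatnonzero(out.chain_id.astype(str) == chain)
                    if i in sel]
            if not cidx:
                continue
            first_res = out.residue_index[cidx[0]]
            last_res = out.residue_index[cidx[-1]]
            for i in cidx:
                if out.residue_index[i] == first_res and str(out.name[i]) == "N":
                    out.charge[i] += 1.0
                if out.residue_index[i] == last_res and str(out.name[i]) == "C":
                    out.charge[i] -= 1.0
    return out


# ---------------------------------------------------------------------------
# rigid perpendicular offsets
# ---------------------------------------------------------------------------

def offset_ligand(
    structure: Structure,
    ligand_group,
    distance: float,
    axis=(0.0, 1.0, 0.0),
) -> Structure:
    """Rigidly translate the ligand group by ``distance`` Å along ``axis``.

    Receptor atoms are untouched; the translation preserves all intra-ligand
    distances exactly. ``axis`` must be a unit vector.
    """
    axis = np.asarray(axis, dtype=float).reshape(3)
    if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-8):
        raise ValueError("offset axis must have unit norm")
    idx = structure.group(ligand_group)
    if idx.size == 0:
        raise InvalidSelectionError("ligand group is empty")
    out = structure.copy()
    out.coords[idx] = out.coords[idx] + float(distance) * axis
    return out


def offset_ladder_structures(
    structure: Structure,
    ligand_group,
    ladder: OffsetLadder | None = None,
) -> dict[float, Structure]:
    """One offset structure per ladder distance (the paper-style 5–55 Å set)."""
    ladder = ladder or OffsetLadder()
    return {
        d: offset_ligand(structure, ligand_group, d, ladder.axis)
        for d in ladder.distances
    }
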