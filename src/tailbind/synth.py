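"""Synthetic inputs with known ground truth.

These generators stand in for the molecular-dynamics ensembles and prepared
microtubule structures of the original study: conformer-mixture trajectories
with known cluster occupancies, trajectories with planted per-frame contact
counts, and point-charge systems with closed-form screened-Coulomb / Born
references. Every generator is fully deterministic under its seed, and each
verifies its own ground truth with the pipeline's oracles before returning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import kabsch_superpose
from .contacts import count_frame_contacts
from .ensemble import TrajectoryEnsemble
from .errors import InvalidSpecError
from .structure import (BETA_TAIL_SEQUENCE, Atom, Structure, build_tail,
                        offset_ligand)
from . import electrostatics as es

__all__ = [
    "ConformerSpec", "PlantedContactSpec",
    "gen_conformer_ensemble", "gen_contact_planted_traj", "gen_charge_system",
]


# ---------------------------------------------------------------------------
# conformer mixtures (clustering ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformerSpec:
    """Mixture of distinct tail conformers plus coordinate noise.

    Conformers are generated by perturbing the backbone dihedrals of an
    extended tail (the disordered-tail analogue of sampling distinct
    conformational states); frames draw a conformer by occupancy and add
    isotropic Gaussian noise.
    """

    n_conformers: int = 5
    occupancies: tuple = (0.35, 0.25, 0.20, 0.15, 0.05)
    noise_sigma: float = 0.25          # Å; keeps intra-conformer RMSD < 0.75 Å
    n_frames: int = 2000
    seed: int = 0
    n_replicates: int = 1
    sequence: str = BETA_TAIL_SEQUENCE
    dihedral_amplitude: float = 80.0   # degrees
    min_separation: float = 4.5        # Å Cα RMSD between conformers
    conformers: np.ndarray | None = None  # explicit (M, A, 3) override

    def __post_init__(self):
        occ = np.asarray(self.occupancies, dtype=float)
        if len(occ) != self.n_conformers:
            raise InvalidSpecError("need one occupancy per conformer")
        if (occ < 0).any() or abs(occ.sum() - 1.0) > 1e-9:
            raise InvalidSpecError("occupancies must be >= 0 and sum to 1")


def _ca_selection(structure: Structure) -> np.ndarray:
    return np.flatnonzero(structure.name.astype(str) == "CA")


def gen_conformer_ensemble(spec: ConformerSpec):
    """Sample a conformer-mixture trajectory ensemble with truth labels.

    Returns ``(ensemble, truth)`` where truth carries per-replicate labels,
    the conformer coordinates, their pairwise Cα RMSD matrix and the nominal
    occupancies. Conformer pairs are guaranteed to differ by more than
    ``min_separation`` Å Cα RMSD (candidates are redrawn otherwise).
    """
    rng = np.random.default_rng(spec.seed)
    base = build_tail(None, spec.sequence, group_name="tail")
    ca = _ca_selection(base)

    if spec.conformers is not None:
        confs = np.asarray(spec.conformers, dtype=float)
        if confs.shape[0] != spec.n_conformers:
            raise InvalidSpecError("conformers array does not match count")
    else:
        nres = len(spec.sequence)
        confs_list = []
        attempts = 0
        while len(confs_list) < spec.n_conformers:
            if attempts > 200 * spec.n_conformers:
                raise InvalidSpecError(
                    "could not draw conformers separated by min_separation")
            attempts += 1
            phi = -120.0 + rng.uniform(-spec.dihedral_amplitude,
                                       spec.dihedral_amplitude, nres)
            psi = 120.0 + rng.uniform(-spec.dihedral_amplitude,
                                      spec.dihedral_amplitude, nres)
            cand = build_tail(None, spec.sequence, phi=phi, psi=psi).coords
            ok = all(
                kabsch_superpose(cand, prev, fit_selection=ca)[2]
                > spec.min_separation
                for prev in confs_list
            )
            if ok:
                confs_list.append(cand)
        confs = np.array(confs_list)

    m = spec.n_conformers
    pair_rmsd = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, _, r = kabsch_superpose(confs[i], confs[j], fit_selection=ca)
            pair_rmsd[i, j] = pair_rmsd[j, i] = r

    replicates, labels = [], []
    occ = np.asarray(spec.occupancies, dtype=float)
    for _ in range(spec.n_replicates):
        lab = rng.choice(m, size=spec.n_frames, p=occ)
        coords = confs[lab] + rng.normal(
            0.0, spec.noise_sigma, size=(spec.n_frames,) + confs.shape[1:])
        replicates.append(coords)
        labels.append(lab)

    ensemble = TrajectoryEnsemble(structure=base, replicates=replicates)
    truth = {
        "labels": labels,
        "conformers": confs,
        "conformer_rmsd": pair_rmsd,
        "occupancies": occ,
        "ca_selection": ca,
        "seed": spec.seed,
    }
    return ensemble, truth


# ---------------------------------------------------------------------------
# planted-contact trajectories (contact ground truth)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContactSpec:
    """Trajectory whose per-frame contact count at the 4 Å rule is planted.

    The template keeps ligand atoms on a widely spaced line; contacting tail
    atoms hover 3 Å above their ligand partner and the rest sit far away, so
    a frame with planted count c yields exactly c atom pairs within cutoff.
    """

    counts: tuple                  # per replicate: sequence of per-frame counts
    seed: int = 0
    n_tail_atoms: int = 20
    n_ligand_atoms: int = 20
    cutoff: float = 4.0
    contact_distance: float = 3.0
    far_distance: float = 40.0
    atom_spacing: float = 10.0
    rotate: bool = False           # random rigid move of both groups per frame
    tail_residue_ids: tuple | None = None  # per tail atom; default 1..n

    def __post_init__(self):
        counts = self.counts
        if counts and np.isscalar(counts[0]):
            counts = (tuple(int(c) for c in counts),)
        else:
            counts = tuple(tuple(int(c) for c in rep) for rep in counts)
        object.__setattr__(self, "counts", counts)
        cmax = min(self.n_tail_atoms, self.n_ligand_atoms)
        for rep in counts:
            for c in rep:
                if not 0 <= c <= cmax:
                    raise InvalidSpecError(
                        f"planted count {c} unachievable for template with "
                        f"{cmax} pairable atoms")


def _planted_structure(spec: PlantedContactSpec) -> Structure:
    atoms = []
    serial = 1
    res_ids = spec.tail_residue_ids or tuple(range(1, spec.n_tail_atoms + 1))
    if len(res_ids) != spec.n_tail_atoms:
        raise InvalidSpecError("tail_residue_ids must cover every tail atom")
    for k in range(spec.n_tail_atoms):
        atoms.append(Atom(serial, "CA", "C", "GLY", int(res_ids[k]), "T",
                          [spec.atom_spacing * k, spec.far_distance, 0.0]))
        serial += 1
    for k in range(spec.n_ligand_atoms):
        atoms.append(Atom(serial, "CA", "C", "GLY", k + 1, "M",
                          [spec.atom_spacing * k, 0.0, 0.0]))
        serial += 1
    nt = spec.n_tail_atoms
    return Structure.from_atoms(atoms, groups={
        "tail": np.arange(nt),
        "ligand": np.arange(nt, nt + spec.n_ligand_atoms),
    })


def _random_rigid(rng):
    # uniform random rotation via QR of a Gaussian matrix
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-50, 50, size=3)
    return q, t


def gen_contact_planted_traj(spec: PlantedContactSpec):
    """Generate a trajectory reproducing planted per-frame contact counts.

    Returns ``(ensemble, truth)``; the generator re-counts every frame with
    the contact engine and raises if any planted count is not reproduced.
    """
    rng = np.random.default_rng(spec.seed)
    base = _planted_structure(spec)
    y_contact = spec.contact_distance
    replicates = []
    for rep_counts in spec.counts:
        frames = np.empty((len(rep_counts), base.n_atoms, 3))
        for f, c in enumerate(rep_counts):
            coords = base.coords.copy()
            coords[:c, 1] = y_contact
            if spec.rotate:
                q, t = _random_rigid(rng)
                coords = coords @ q.T + t
            frames[f] = coords
        replicates.append(frames)
    ensemble = TrajectoryEnsemble(structure=base, replicates=replicates)

    for rep_counts, frames in zip(spec.counts, ensemble.replicates):
        for f, c in enumerate(rep_counts):
            got = count_frame_contacts(frames[f], base, "tail", "ligand",
                                       cutoff=spec.cutoff).pair_count
            if got != c:
                raise InvalidSpecError(
                    f"template failed to plant count {c} (got {got}) at "
                    f"frame {f}")
    truth = {"counts": [np.array(rc, dtype=int) for rc in spec.counts],
             "seed": spec.seed, "cutoff": spec.cutoff}
    return ensemble, truth


# ---------------------------------------------------------------------------
# point-charge validation systems (electrostatics ground truth)
# ---------------------------------------------------------------------------

def _point_structure(entries, groups):
    """entries: list of (name, chain, position, charge, radius)."""
    atoms = [
        Atom(i + 1, name, name[0], "ION", i + 1, chain, pos,
             charge=q, radius=r)
        for i, (name, chain, pos, q, r) in enumerate(entries)
    ]
    return Structure.from_atoms(atoms, groups=groups)


def gen_charge_system(preset: str, **kwargs) -> dict:
    """Point-charge systems with analytic references.

    Presets
    -------
    ``born_ion``
        One charged sphere (q=+1, radius 2 Å); reference: Born reaction
        potential at the centre for ε 2/80.
    ``opposite_pair``
        +1 and −1 point charges ``separation`` Å apart in homogeneous
        solvent; reference: screened-Coulomb force vector on the target.
    ``mirror_pair``
        Two +1 sources mirror-symmetric about the target's y-axis; reference:
        perpendicular (x, z) force components exactly zero.
    ``tail_ligand_flip``
        A line of negative tail charges spanning the receptor surface and a
        positive ligand charge on the offset ladder; the analytic
        screened-Coulomb superposition gives an attractive (negative)
        perpendicular force at large offsets and a repulsive (positive) one
        at small offsets — the soft-landing sign signature.
    """
    t = kwargs.pop("temperature", es.DEFAULT_TEMPERATURE)

    if preset == "born_ion":
        q = kwargs.pop("q", 1.0)
        radius = kwargs.pop("radius", 2.0)
        eps_in = kwargs.pop("eps_in", es.DEFAULT_EPS_IN)
        eps_out = kwargs.pop("eps_out", es.DEFAULT_EPS_OUT)
        structure = _point_structure(
            [("ION", "I", [0.0, 0.0, 0.0], q, radius)],
            groups={"ion": np.array([0])})
        return {
            "preset": preset,
            "structure": structure,
            "eps_in": eps_in, "eps_out": eps_out, "ionic_strength": 0.0,
            "reference": {
                "reaction_potential_kT_e": es.born_reaction_potential(
                    q, radius, eps_in, eps_out, temperature=t),
            },
        }

    if preset in ("opposite_pair", "mirror_pair"):
        eps = kwargs.pop("eps", es.DEFAULT_EPS_OUT)
        ionic = kwargs.pop("ionic_strength", 0.0)
        kappa = es.debye_kappa(ionic, eps, t) if ionic > 0 else 0.0
        tiny = 0.1  # radii small enough that the dielectric stays homogeneous
        if preset == "opposite_pair":
            sep = float(kwargs.pop("separation", 20.0))
            entries = [("SRC", "S", [0.0, 0.0, 0.0], +1.0, tiny),
                       ("TGT", "T", [0.0, sep, 0.0], -1.0, tiny)]
            groups = {"source": np.array([0]), "target": np.array([1])}
            ref_force = es.screened_coulomb_force(
                +1.0, -1.0, np.array([0.0, sep, 0.0]), eps, kappa,
                temperature=t)
        else:
            x0 = float(kwargs.pop("half_separation", 8.0))
            y0 = float(kwargs.pop("height", 15.0))
            entries = [("SRC", "S", [-x0, y0, 0.0], +1.0, tiny),
                       ("SRC", "S", [+x0, y0, 0.0], +1.0, tiny),
                       ("TGT", "T", [0.0, 0.0, 0.0], -1.0, tiny)]
            groups = {"source": np.array([0, 1]), "target": np.array([2])}
            ref_force = (
                es.screened_coulomb_force(+1.0, -1.0,
                                          np.array([x0, -y0, 0.0]), eps,
                                          kappa, temperature=t)
                + es.screened_coulomb_force(+1.0, -1.0,
                                            np.array([-x0, -y0, 0.0]), eps,
                                            kappa, temperature=t))
            assert abs(ref_force[0]) < 1e-12 and abs(ref_force[2]) < 1e-12
        structure = _point_structure(entries, groups)
        return {
            "preset": preset,
            "structure": structure,
            "eps_in": eps, "eps_out": eps, "ionic_strength": ionic,
            "kappa": kappa,
            "reference": {"force_kcal_mol_A": ref_force},
        }

    if preset == "tail_ligand_flip":
        eps = kwargs.pop("eps", es.DEFAULT_EPS_OUT)
        ionic = kwargs.pop("ionic_strength", es.DEFAULT_IONIC_STRENGTH)
        distances = tuple(kwargs.pop("distances", (5.0, 15.0, 25.0, 35.0,
                                                   45.0, 55.0)))
        kappa = es.debye_kappa(ionic, eps, t) if ionic > 0 else 0.0
        tiny = 0.1
        tail_y = np.arange(2.0, 21.0, 2.0)   # charges spanning the tail reach
        tail_x = 4.0                         # lateral offset avoids overlap
        bound_y = 3.0                        # ligand bound position
        q_lig = +2.0
        entries = [("TC", "E", [tail_x, y, 0.0], -1.0, tiny) for y in tail_y]
        entries.append(("LIG", "M", [0.0, bound_y, 0.0], q_lig, tiny))
        n = len(tail_y)
        base = _point_structure(entries, groups={
            "Ehooks": np.arange(n), "MTBD": np.array([n])})
        structures, analytic = {}, {}
        for d in distances:
            s = offset_ligand(base, "MTBD", d, axis=(0.0, 1.0, 0.0))
            structures[float(d)] = s
            tpos = s.coords[n]
            f = np.zeros(3)
            for y in tail_y:
                f = f + es.screened_coulomb_force(
                    -1.0, q_lig, tpos - np.array([tail_x, y, 0.0]), eps,
                    kappa, temperature=t)
            analytic[float(d)] = f
        # the preset's own sign contract, checked before anyone uses it
        dmin, dmax = min(distances), max(distances)
        if not (analytic[dmin][1] > 0 and analytic[dmax][1] < 0):
            raise InvalidSpecError(
                "tail_ligand_flip geometry does not flip the perpendicular "
                "force sign across the ladder")
        return {
            "preset": preset,
            "structures": structures,
            "analytic_forces": analytic,
            "eps_in": eps, "eps_out": eps, "ionic_strength": ionic,
            "kappa": kappa,
            "source_group": "Ehooks", "target_group": "MTBD",
            "axis": np.array([0.0, 1.0, 0.0]),
        }

    raise InvalidSpecError(f"unknown charge-system preset {preset!r}")
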