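"""Replicated trajectory ensembles over a fixed topology."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError
from .structure import Structure

__all__ = ["TrajectoryEnsemble"]


@dataclass
class TrajectoryEnsemble:
    """Ordered frames of coordinates for a fixed topology, per replicate run.

    ``replicates`` is a list of ``(n_frames, n_atoms, 3)`` arrays; every
    replicate must share the topology's atom count and a common frame count
    so frame-wise averaging across runs is well defined.
    """

    structure: Structure
    replicates: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self):
        reps = []
        for r, arr in enumerate(self.replicates):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise InvalidSpecError(
                    f"replicate {r} must have shape (frames, atoms, 3)")
            if arr.shape[1] != self.structure.n_atoms:
                raise InvalidSpecError(
                    f"replicate {r} has {arr.shape[1]} atoms, topology has "
                    f"{self.structure.n_atoms}")
            reps.append(arr)
        if len({a.shape[0] for a in reps} or {0}) > 1:
            raise InvalidSpecError(
                "replicates have mismatched frame counts: "
                + str([a.shape[0] for a in reps]))
        self.replicates = reps

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def n_frames(self) -> int:
        return self.replicates[0].shape[0] if self.replicates else 0

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def pooled(self) -> np.ndarray:
        """All frames stacked replicate-major: shape (R * F, A, 3)."""
        return np.concatenate(self.replicates, axis=0) if self.replicates \
            else np.empty((0, self.n_atoms, 3))

    def frame_window(self, start_fraction: float = 0.5,
                     stop_fraction: float = 1.0) -> "TrajectoryEnsemble":
        """Restrict to a fractional frame window of every replicate.

        The default keeps the second half of each run, mirroring analysis of
        the equilibrated tail of a simulation.
        """
        if not 0.0 <= start_fraction < stop_fraction <= 1.0:
            raise InvalidSpecError("need 0 <= start < stop <= 1")
        lo = int(round(start_fraction * self.n_frames))
        hi = int(round(stop_fraction * self.n_frames))
        return TrajectoryEnsemble(
            structure=self.structure,
            replicates=[a[lo:hi] for a in self.replicates],
        )

    def subset_atoms(self, indices) -> "TrajectoryEnsemble":
        idx = self.structure.group(indices)
        sub = self.structure.copy()
        keep = np.zeros(sub.n_atoms, dtype=bool)
        keep[idx] = True
        remap = np.cumsum(keep) - 1
        groups = {
            k: remap[v[keep[v]]] for k, v in sub.groups.items()
        }
        sub = Structure(
            serial=sub.serial[idx], name=sub.name[idx],
            element=sub.element[idx], residue_name=sub.residue_name[idx],
            residue_index=sub.residue_index[idx], chain_id=sub.chain_id[idx],
            coords=sub.coords[idx], charge=sub.charge[idx],
            radius=sub.radius[idx], groups=groups,
        )
        return TrajectoryEnsemble(
            structure=sub, replicates=[a[:, idx] for a in self.replicates])
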