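"""Conformational clustering of tail ensembles and free/bound comparison.

Frames are superposed with the Kabsch algorithm (fit selection and RMSD
selection may differ: the structured body anchors the fit while the RMSD is
evaluated over all selected atoms, so the tail's orientation relative to the
body is retained). The pairwise Cα RMSD matrix feeds the Daura clustering
algorithm: the frame with the most neighbours within the cutoff becomes a
cluster centre, the centre and its neighbours are removed, and the step
repeats until no frames remain. Free-state clusters are matched to bound-state
clusters by minimal representative RMSD, and occupancy correspondence is
summarised by a contact-weighted linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidSelectionError, InvalidSpecError

__all__ = [
    "RmsdMatrix", "ClusterSet", "Correspondence", "RegressionResult",
    "kabsch_superpose", "pairwise_rmsd", "rmsd_matrix", "daura_cluster",
    "top_clusters", "correspond_clusters", "occupancy_regression",
]

DEFAULT_CLUSTER_CUTOFF = 1.5  # Å, Cα RMSD
DEFAULT_TOP_K = 5


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _check_fit_coords(p: np.ndarray):
    if len(p) < 3:
        raise DegenerateInputError("need >= 3 fit atoms")
    s = np.linalg.svd(p - p.mean(axis=0), compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise DegenerateInputError(
            "fit atoms are collinear or coincident; superposition is "
            "underdetermined")


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection=None,
    rmsd_selection=None,
):
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``rotation @ x + translation`` maps mobile coordinates into the reference
    frame. The transform minimises the deviation over ``fit_selection``; the
    RMSD is evaluated over ``rmsd_selection`` after applying it. Both default
    to all atoms. The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float).reshape(-1, 3)
    reference = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mobile.shape != reference.shape:
        raise InvalidSpecError("mobile and reference must match in shape")
    fit = np.arange(len(mobile)) if fit_selection is None \
        else np.asarray(fit_selection, dtype=int)
    rsel = fit if rmsd_selection is None and fit_selection is not None \
        else (np.arange(len(mobile)) if rmsd_selection is None
              else np.asarray(rmsd_selection, dtype=int))
    if fit.size == 0 or rsel.size == 0:
        raise InvalidSelectionError("empty selection")
    _check_fit_coords(mobile[fit])

    cm = mobile[fit].mean(axis=0)
    cr = reference[fit].mean(axis=0)
    p = mobile[fit] - cm
    q = reference[fit] - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u) * np.linalg.det(vt))
    v = vt.T.copy()
    v[:, 2] *= d
    rot = v @ u.T
    trans = cr - rot @ cm

    moved = (mobile[rsel] - cm) @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference[rsel]) ** 2,
                                        axis=1))))
    return rot, trans, rmsd


# ---------------------------------------------------------------------------
# pairwise RMSD matrix (batched Kabsch via the trace identity)
# ---------------------------------------------------------------------------

@dataclass
class RmsdMatrix:
    """Symmetric matrix of superposed RMSDs between frames (Å)."""

    n_frames: int
    values: np.ndarray
    fit_selection: np.ndarray | None = None
    rmsd_selection: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n_frames, self.n_frames):
            raise InvalidSpecError("RmsdMatrix.values must be n x n")
        if (v < -1e-12).any() or not np.allclose(np.diag(v), 0, atol=1e-9):
            raise InvalidSpecError(
                "RmsdMatrix must be non-negative with a zero diagonal")
        self.values = v


def pairwise_rmsd(
    frames: np.ndarray,
    pairs_i: np.ndarray,
    pairs_j: np.ndarray,
    fit_selection=None,
    rmsd_selection=None,
) -> np.ndarray:
    """Superposed RMSD for an arbitrary list of frame pairs, batched.

    Uses the Kabsch trace identity
    ``rmsd² = (|A|² + |B|² − 2·tr(R·AᵀB)) / n`` with the optimal rotation from
    a batched 3×3 SVD, so no per-atom rotation is ever applied.
    """
    x = np.asarray(frames, dtype=float)
    n, natoms, _ = x.shape
    fit = np.arange(natoms) if fit_selection is None \
        else np.asarray(fit_selection, dtype=int)
    rsel = np.arange(natoms) if rmsd_selection is None \
        else np.asarray(rmsd_selection, dtype=int)
    if fit.size == 0 or rsel.size == 0:
        raise InvalidSelectionError("empty selection")
    _check_fit_coords(x[0, fit])

    cf = x[:, fit].mean(axis=1, keepdims=True)
    af = x[:, fit] - cf          # fit coords, fit-centred
    ar = x[:, rsel] - cf         # rmsd coords, centred on the fit centroid
    g = np.einsum("nam,nam->n", ar, ar)
    same = fit.size == rsel.size and np.array_equal(fit, rsel)

    ii = np.asarray(pairs_i, dtype=int)
    jj = np.asarray(pairs_j, dtype=int)
    out = np.empty(len(ii))
    chunk = 200_000
    for lo in range(0, len(ii), chunk):
        ci = ii[lo:lo + chunk]
        cj = jj[lo:lo + chunk]
        h = np.einsum("pam,pan->pmn", af[ci], af[cj])
        # closed-form 3x3 determinant: cheaper than LU on large batches
        det = (h[:, 0, 0] * (h[:, 1, 1] * h[:, 2, 2] - h[:, 1, 2] * h[:, 2, 1])
               - h[:, 0, 1] * (h[:, 1, 0] * h[:, 2, 2] - h[:, 1, 2] * h[:, 2, 0])
               + h[:, 0, 2] * (h[:, 1, 0] * h[:, 2, 1] - h[:, 1, 1] * h[:, 2, 0]))
        d = np.where(det < 0, -1.0, 1.0)
        if same:
            # singular values via the spectrum of HᵀH (no rotation needed)
            ev = np.linalg.eigvalsh(np.einsum("pmk,pnk->pmn", h, h))
            s = np.sqrt(np.clip(ev, 0.0, None))[:, ::-1]
            tr = s[:, 0] + s[:, 1] + d * s[:, 2]
        else:
            u, s, vt = np.linalg.svd(h)
            v = vt.transpose(0, 2, 1).copy()
            v[:, :, 2] *= d[:, None]
            rot = v @ u.transpose(0, 2, 1)
            m = np.einsum("pam,pan->pmn", ar[ci], ar[cj])
            tr = np.einsum("pmn,pnm->p", rot, m)
        d2 = (g[ci] + g[cj] - 2.0 * tr) / rsel.size
        out[lo:lo + chunk] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def rmsd_matrix(
    frames: np.ndarray,
    fit_selection=None,
    rmsd_selection=None,
) -> RmsdMatrix:
    """All-pairs superposed RMSD matrix over an ensemble of frames."""
    x = np.asarray(frames, dtype=float)
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = np.zeros((n, n))
    if len(iu):
        r = pairwise_rmsd(x, iu, ju, fit_selection, rmsd_selection)
        vals[iu, ju] = r
        vals[ju, iu] = r
    return RmsdMatrix(
        n_frames=n, values=vals,
        fit_selection=None if fit_selection is None
        else np.asarray(fit_selection, dtype=int),
        rmsd_selection=None if rmsd_selection is None
        else np.asarray(rmsd_selection, dtype=int),
    )


# ---------------------------------------------------------------------------
# Daura clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Daura clusters ordered by decreasing size.

    ``occupancies`` are fractions of *all* ``n_frames`` frames, so after
    restricting to the top k the unclustered remainder mass stays visible.
    """

    clusters: list  # [(member frame indices, representative frame index)]
    n_frames: int
    cutoff: float
    cumulative_occupancy: float | None = None

    def __post_init__(self):
        seen: set[int] = set()
        for members, rep in self.clusters:
            mem = set(np.asarray(members, dtype=int).tolist())
            if rep not in mem:
                raise InvalidSpecError("representative must be a member")
            if mem & seen:
                raise InvalidSpecError("clusters must be disjoint")
            seen |= mem

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(m) for m, _ in self.clusters], dtype=int)

    @property
    def occupancies(self) -> np.ndarray:
        return self.sizes / self.n_frames

    @property
    def representatives(self) -> np.ndarray:
        return np.array([rep for _, rep in self.clusters], dtype=int)

    def labels(self) -> np.ndarray:
        """Per-frame cluster id (−1 for frames outside the retained clusters)."""
        lab = np.full(self.n_frames, -1, dtype=int)
        for cid, (members, _) in enumerate(self.clusters):
            lab[np.asarray(members, dtype=int)] = cid
        return lab

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": np.arange(len(self.clusters)),
            "size": self.sizes,
            "occupancy": self.occupancies,
            "representative_frame": self.representatives,
        })


def daura_cluster(matrix: RmsdMatrix | np.ndarray,
                  cutoff: float = DEFAULT_CLUSTER_CUTOFF) -> ClusterSet:
    """Greedy neighbour-count clustering on an RMSD matrix.

    Repeatedly the frame with the most neighbours within ``cutoff``
    (boundary inclusive, self included) becomes a centre; the centre and its
    neighbours form a cluster and are removed. Neighbour-count ties are broken
    toward the lowest frame index so results are platform-deterministic.
    Every frame ends up in exactly one cluster.
    """
    values = matrix.values if isinstance(matrix, RmsdMatrix) \
        else np.asarray(matrix, dtype=float)
    n = values.shape[0]
    adj = values <= cutoff
    np.fill_diagonal(adj, True)
    alive = np.ones(n, dtype=bool)
    clusters = []
    while alive.any():
        counts = np.where(alive, (adj & alive[None, :]).sum(axis=1), -1)
        center = int(np.argmax(counts))  # first max -> lowest frame index
        members = np.flatnonzero(adj[center] & alive)
        clusters.append((members, center))
        alive[members] = False
    # extraction order is already non-increasing in size with the lowest-centre
    # tie rule; a stable sort keeps that order canonical
    order = np.argsort([-len(m) for m, _ in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    return ClusterSet(clusters=clusters, n_frames=n, cutoff=float(cutoff))


def top_clusters(cluster_set: ClusterSet, k: int = DEFAULT_TOP_K) -> ClusterSet:
    """Restrict to the k most populated clusters.

    Occupancies stay relative to all frames; ``cumulative_occupancy`` reports
    the retained mass (1 − it is the paper-style "unclustered" remainder).
    A ``k`` beyond the cluster count returns every cluster.
    """
    if k < 1:
        raise InvalidSpecError("k must be >= 1")
    kept = cluster_set.clusters[:k]
    cum = float(sum(len(m) for m, _ in kept) / cluster_set.n_frames)
    return ClusterSet(clusters=kept, n_frames=cluster_set.n_frames,
                      cutoff=cluster_set.cutoff, cumulative_occupancy=cum)


# ---------------------------------------------------------------------------
# free/bound cluster correspondence
# ---------------------------------------------------------------------------

@dataclass
class Correspondence:
    """Minimal-RMSD pairing of bound clusters to free clusters."""

    pairs: list  # [(free cluster id, bound cluster id, representative RMSD Å)]
    rmsd_table: np.ndarray = field(default=None)  # (n_free, n_bound)

    def as_frame(self, free: ClusterSet | None = None,
                 bound: ClusterSet | None = None,
                 nc: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for f, b, r in self.pairs:
            row = {"free_cluster": f, "bound_cluster": b,
                   "representative_rmsd": r}
            if free is not None:
                row["free_occupancy"] = free.occupancies[f]
            if bound is not None:
                row["bound_occupancy"] = bound.occupancies[b]
            if nc is not None:
                row["Nc"] = nc[b]
            rows.append(row)
        return pd.DataFrame(rows)


def correspond_clusters(
    free: ClusterSet,
    bound: ClusterSet,
    free_frames: np.ndarray,
    bound_frames: np.ndarray,
    fit_selection=None,
    rmsd_selection=None,
) -> Correspondence:
    """Map every bound cluster to its minimal-representative-RMSD free cluster.

    Ties are broken toward the more occupied free cluster. The frame arrays
    provide the representatives' coordinates and must share atom topology.
    """
    if not free.clusters or not bound.clusters:
        raise InvalidSpecError("both cluster sets must be non-empty")
    free_frames = np.asarray(free_frames, dtype=float)
    bound_frames = np.asarray(bound_frames, dtype=float)
    if free_frames.shape[1:] != bound_frames.shape[1:]:
        raise InvalidSpecError(
            "free and bound ensembles have incomparable topologies")
    table = np.zeros((len(free.clusters), len(bound.clusters)))
    for fi, frep in enumerate(free.representatives):
        for bi, brep in enumerate(bound.representatives):
            _, _, r = kabsch_superpose(
                bound_frames[brep], free_frames[frep],
                fit_selection=fit_selection, rmsd_selection=rmsd_selection)
            table[fi, bi] = r
    pairs = []
    for bi in range(len(bound.clusters)):
        col = table[:, bi]
        best = np.flatnonzero(col == col.min())
        if len(best) > 1:  # toward the more occupied free cluster
            best = best[np.argsort(-free.occupancies[best], kind="stable")]
        fi = int(best[0])
        pairs.append((fi, bi, float(col[fi])))
    return Correspondence(pairs=pairs, rmsd_table=table)


# ---------------------------------------------------------------------------
# contact-weighted occupancy regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    weights: np.ndarray

    def __post_init__(self):
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise InvalidSpecError("R² must lie in [0, 1]")


def occupancy_regression(
    free_occupancy: np.ndarray,
    bound_occupancy: np.ndarray,
    weights: np.ndarray,
) -> RegressionResult:
    """Weighted least-squares line through (free, bound) occupancy pairs.

    Weights are per-point contact counts Nc; with equal weights the fit
    reduces to ordinary least squares. The weighted R² is reported.
    """
    import statsmodels.api as sm

    x = np.asarray(free_occupancy, dtype=float)
    y = np.asarray(bound_occupancy, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.size < 2:
        raise InvalidSpecError("need at least 2 points")
    if (w < 0).any() or not (w > 0).any():
        raise InvalidSpecError("weights must be >= 0 and not all zero")
    if np.ptp(x[w > 0]) == 0:
        raise DegenerateInputError("all weighted x values are equal")
    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(min(max(res.rsquared, 0.0), 1.0)),
        weights=w,
    )
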