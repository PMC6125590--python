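"""Superposition, Daura clustering, correspondence and weighted regression."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tailbind.clustering import (ClusterSet, correspond_clusters,
                                 daura_cluster, kabsch_superpose,
                                 occupancy_regression, rmsd_matrix,
                                 top_clusters)
from tailbind.errors import DegenerateInputError, InvalidSpecError


def random_rotation(rng):
    return Rotation.random(random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()


class TestKabsch:
    def test_self_rmsd_zero(self, rng):
        x = rng.normal(size=(12, 3))
        _, _, r = kabsch_superpose(x, x)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_rmsd_zero(self, rng):
        x = rng.normal(size=(15, 3)) * 5
        q = random_rotation(rng)
        y = x @ q.T + np.array([3.0, -7.0, 11.0])
        rot, trans, r = kabsch_superpose(y, x)
        assert r == pytest.approx(0.0, abs=1e-8)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose((rot @ y.T).T + trans, x, atol=1e-8)

    def test_matches_numerical_minimization_oracle(self, rng):
        """Direct optimisation over rotation vectors must find the same
        minimum RMSD as the closed-form superposition."""
        x = rng.normal(size=(10, 3)) * 3
        y = rng.normal(size=(10, 3)) * 3
        _, _, r_kabsch = kabsch_superpose(x, y)

        xc = x - x.mean(0)
        yc = y - y.mean(0)

        def objective(v):
            rot = Rotation.from_rotvec(v).as_matrix()
            return np.sqrt(np.mean(np.sum((xc @ rot.T - yc) ** 2, axis=1)))

        best = min(
            minimize(objective, v0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-12,
                              "maxiter": 20000}).fun
            for v0 in [np.zeros(3), [3, 0, 0], [0, 3, 0], [1.5, 1.5, -1.5]]
        )
        assert r_kabsch == pytest.approx(best, abs=1e-6)

    def test_collinear_fit_set_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateInputError):
            kabsch_superpose(line, line + 1.0)

    def test_distinct_fit_and_rmsd_selections(self, rng):
        x = rng.normal(size=(20, 3)) * 4
        q = random_rotation(rng)
        y = x @ q.T + 5.0
        # fit on the first half only; rmsd over the second half still ~0
        _, _, r = kabsch_superpose(y, x, fit_selection=np.arange(10),
                                   rmsd_selection=np.arange(10, 20))
        assert r == pytest.approx(0.0, abs=1e-8)


class TestRmsdMatrix:
    def test_identical_frames_zero_matrix(self, rng):
        x = np.repeat(rng.normal(size=(1, 8, 3)), 5, axis=0)
        m = rmsd_matrix(x)
        # the batched trace identity cancels large terms; residue is ~1e-8 Å
        np.testing.assert_allclose(m.values, 0.0, atol=1e-6)

    def test_symmetry_and_diagonal(self, rng):
        x = rng.normal(size=(9, 11, 3)) * 3
        m = rmsd_matrix(x)
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_allclose(np.diag(m.values), 0.0, atol=1e-12)

    def test_entries_match_pairwise_kabsch(self, rng):
        x = rng.normal(size=(10, 14, 3)) * 3
        fit = np.arange(7)
        rsel = np.arange(14)
        m = rmsd_matrix(x, fit_selection=fit, rmsd_selection=rsel)
        for i in range(10):
            for j in range(i + 1, 10):
                _, _, r = kabsch_superpose(x[i], x[j], fit_selection=fit,
                                           rmsd_selection=rsel)
                assert m.values[i, j] == pytest.approx(r, abs=1e-8)


def daura_reference(values, cutoff):
    """Independent literal transcription of the clustering algorithm."""
    n = len(values)
    remaining = set(range(n))
    clusters = []
    while remaining:
        best_center, best_neighbors = None, None
        for i in sorted(remaining):
            nbrs = {j for j in remaining if values[i][j] <= cutoff}
            if best_neighbors is None or len(nbrs) > len(best_neighbors):
                best_center, best_neighbors = i, nbrs
        clusters.append((frozenset(best_neighbors), best_center))
        remaining -= best_neighbors
    clusters.sort(key=lambda c: -len(c[0]))
    return clusters


def random_rmsd_like_matrix(rng, n=30):
    v = np.abs(rng.normal(2.0, 1.5, size=(n, n)))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v


class TestDaura:
    def test_all_within_cutoff_single_cluster(self):
        v = np.full((6, 6), 0.5)
        np.fill_diagonal(v, 0.0)
        cs = daura_cluster(v, cutoff=1.5)
        assert len(cs.clusters) == 1
        assert cs.occupancies[0] == pytest.approx(1.0)

    def test_all_beyond_cutoff_singletons(self):
        v = np.full((7, 7), 9.0)
        np.fill_diagonal(v, 0.0)
        cs = daura_cluster(v, cutoff=1.5)
        assert len(cs.clusters) == 7
        assert (cs.sizes == 1).all()

    def test_matches_literal_transcription(self, rng):
        for _ in range(10):
            v = random_rmsd_like_matrix(rng)
            cs = daura_cluster(v, cutoff=1.5)
            ref = daura_reference(v.tolist(), 1.5)
            got = [(frozenset(m.tolist()), rep) for m, rep in cs.clusters]
            assert got == ref

    def test_partition_covers_all_frames(self, rng):
        v = random_rmsd_like_matrix(rng, n=40)
        cs = daura_cluster(v, cutoff=2.0)
        assert sorted(np.concatenate(
            [m for m, _ in cs.clusters]).tolist()) == list(range(40))

    def test_invariant_under_frame_permutation(self, rng):
        """Well-separated neighbourhoods give the same partition whatever the
        frame order (ties inside a block pick different centres but the same
        member set)."""
        sizes = (9, 7, 5, 3, 1)
        n = sum(sizes)
        v = np.full((n, n), 9.0)
        start = 0
        for s in sizes:
            blk = rng.uniform(0.2, 1.2, size=(s, s))
            v[start:start + s, start:start + s] = (blk + blk.T) / 2
            start += s
        np.fill_diagonal(v, 0.0)
        perm = rng.permutation(n)
        cs1 = daura_cluster(v, cutoff=1.5)
        cs2 = daura_cluster(v[np.ix_(perm, perm)], cutoff=1.5)
        parts1 = sorted(sorted(m.tolist()) for m, _ in cs1.clusters)
        parts2 = sorted(sorted(perm[m].tolist()) for m, _ in cs2.clusters)
        assert parts1 == parts2

    def test_cluster_count_monotone_in_cutoff(self, rng):
        v = random_rmsd_like_matrix(rng, n=30)
        counts = [len(daura_cluster(v, cutoff=c).clusters)
                  for c in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts, reverse=True)


class TestTopClusters:
    def test_k_beyond_count_returns_all(self):
        v = np.full((4, 4), 9.0)
        np.fill_diagonal(v, 0.0)
        cs = top_clusters(daura_cluster(v, 1.5), k=10)
        assert len(cs.clusters) == 4
        assert cs.cumulative_occupancy == pytest.approx(1.0)

    def test_equal_size_order_by_lowest_center(self):
        # two disjoint pairs: frames {0,1} and {2,3}
        v = np.full((4, 4), 9.0)
        v[0, 1] = v[1, 0] = 0.5
        v[2, 3] = v[3, 2] = 0.5
        np.fill_diagonal(v, 0.0)
        cs = top_clusters(daura_cluster(v, 1.5), k=2)
        assert cs.representatives.tolist() == [0, 2]

    def test_remainder_mass_visible(self):
        v = np.full((10, 10), 9.0)
        v[:4, :4] = 0.5
        np.fill_diagonal(v, 0.0)
        cs = top_clusters(daura_cluster(v, 1.5), k=1)
        assert cs.occupancies[0] == pytest.approx(0.4)
        assert cs.cumulative_occupancy == pytest.approx(0.4)


class TestCorrespondence:
    def test_identity_mapping_for_equal_sets(self, rng):
        frames = rng.normal(size=(6, 10, 3)) * 5
        cs = daura_cluster(rmsd_matrix(frames), cutoff=0.1)
        corr = correspond_clusters(cs, cs, frames, frames)
        for f, b, r in corr.pairs:
            assert f == b
            assert r == pytest.approx(0.0, abs=1e-8)

    def test_single_cluster_each_pairs_uniquely(self, rng):
        frames = np.repeat(rng.normal(size=(1, 8, 3)), 4, axis=0)
        cs = daura_cluster(rmsd_matrix(frames), cutoff=1.0)
        corr = correspond_clusters(cs, cs, frames, frames)
        assert corr.pairs == [(0, 0, pytest.approx(0.0, abs=1e-9))]

    def test_mapping_equals_exhaustive_argmin_table(self, rng):
        free_frames = rng.normal(size=(3, 12, 3)) * 6
        bound_frames = free_frames[[2, 0, 1]] + rng.normal(
            0, 0.1, size=(3, 12, 3))
        big = np.full((3, 3), 99.0)
        np.fill_diagonal(big, 0.0)
        free = daura_cluster(big, cutoff=1.0)
        bound = daura_cluster(big, cutoff=1.0)
        corr = correspond_clusters(free, bound, free_frames, bound_frames)
        table = np.array([
            [kabsch_superpose(bound_frames[b], free_frames[f])[2]
             for b in range(3)] for f in range(3)
        ])
        for f, b, r in corr.pairs:
            assert f == int(np.argmin(table[:, b]))
            assert r == pytest.approx(table[f, b], abs=1e-10)

    def test_topology_mismatch_rejected(self, rng):
        f1 = rng.normal(size=(2, 10, 3))
        f2 = rng.normal(size=(2, 11, 3))
        big = np.full((2, 2), 99.0)
        np.fill_diagonal(big, 0.0)
        cs = daura_cluster(big, cutoff=1.0)
        with pytest.raises(InvalidSpecError):
            correspond_clusters(cs, cs, f1, f2)


def normal_equations_wls(x, y, w):
    """Closed-form weighted least squares with weighted R²."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    ss_res = (w * resid ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    return slope, intercept, 1.0 - ss_res / ss_tot


class TestOccupancyRegression:
    def test_matches_normal_equations(self, rng):
        x = rng.uniform(0, 0.5, 8)
        y = 0.7 * x + 0.05 + rng.normal(0, 0.05, 8)
        w = rng.uniform(0.5, 20.0, 8)
        res = occupancy_regression(x, y, w)
        slope, intercept, r2 = normal_equations_wls(x, y, w)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_equal_weights_reduce_to_ols(self, rng):
        x = rng.uniform(0, 1, 10)
        y = rng.uniform(0, 1, 10)
        res_w = occupancy_regression(x, y, np.full(10, 3.7))
        slope, intercept = np.polyfit(x, y, 1)
        assert res_w.slope == pytest.approx(slope, abs=1e-10)
        assert res_w.intercept == pytest.approx(intercept, abs=1e-10)

    def test_collinear_points_r2_one(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        y = 2.0 * x - 0.05
        res = occupancy_regression(x, y, np.array([1.0, 5.0, 2.0, 9.0]))
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateInputError):
            occupancy_regression([0.2, 0.2, 0.2], [0.1, 0.2, 0.3],
                                 [1.0, 1.0, 1.0])
        with pytest.raises(InvalidSpecError):
            occupancy_regression([0.1, 0.2], [0.1, 0.2], [0.0, 0.0])
        with pytest.raises(InvalidSpecError):
            occupancy_regression([0.1], [0.2], [1.0])


def test_clusterset_rejects_overlapping_clusters():
    with pytest.raises(InvalidSpecError):
        ClusterSet(clusters=[(np.array([0, 1]), 0), (np.array([1, 2]), 2)],
                   n_frames=3, cutoff=1.5)
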