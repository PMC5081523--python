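"""Structural measurements: satisfaction, Kendall, radial shells,
macrodomains, Procrustes, MDS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import cdist

from chromosteer import analysis
from chromosteer.analysis import (Partition, dissimilarity_from_distances,
                                  distance_matrix, kendall_vs_hic,
                                  macrodomain_partition, mds_reconstruct,
                                  overlap_significance, partition_objective,
                                  partition_overlap, procrustes_rmsd,
                                  radial_profiles, random_partition,
                                  satisfaction_fractions)
from chromosteer.steering import Restraint, RestraintSet


def _rset(pairs, coords_n=100):
    rs = [Restraint(0, a, b, 50, 0.01, 0.1) for a, b in pairs]
    return RestraintSet(rs)


class TestSatisfaction:
    def test_coincident_regions_fully_satisfied(self):
        coords = np.zeros((66, 3))
        rset = _rset([((0, 33), (33, 66))])
        fr = satisfaction_fractions(coords, rset)
        assert all(v == 1.0 for v in fr.values())

    def test_distant_regions_unsatisfied(self):
        coords = np.zeros((66, 3))
        coords[33:, 0] = 10_000.0
        fr = satisfaction_fractions(coords, _rset([((0, 33), (33, 66))]))
        assert all(v == 0.0 for v in fr.values())

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=150.0, size=(100, 3))
        pairs = [((0, 10), (50, 60)), ((10, 20), (80, 90)),
                 ((20, 30), (30, 40)), ((5, 15), (60, 70)),
                 ((40, 50), (90, 100))]
        rset = _rset(pairs)
        fr = satisfaction_fractions(coords, rset, (120.0, 240.0, 480.0))
        for co in (120.0, 240.0, 480.0):
            com = np.mean([
                np.linalg.norm(coords[a[0]:a[1]].mean(0)
                               - coords[b[0]:b[1]].mean(0)) <= co
                for a, b in pairs])
            close = np.mean([
                cdist(coords[a[0]:a[1]], coords[b[0]:b[1]]).min() <= co
                for a, b in pairs])
            assert fr[("com", co)] == com
            assert fr[("closest", co)] == close

    def test_monotonicity_invariants(self):
        rng = np.random.default_rng(1)
        for rep in range(5):
            coords = rng.normal(scale=200.0, size=(100, 3))
            pairs = [((0, 10), (50, 60)), ((20, 30), (70, 80))]
            fr = satisfaction_fractions(coords, _rset(pairs))
            assert fr[("com", 120.0)] <= fr[("com", 240.0)] <= fr[("com", 480.0)]
            for co in (120.0, 240.0, 480.0):
                assert fr[("closest", co)] >= fr[("com", co)]


class TestDistanceMatrix:
    def test_collinear_equal_spacing(self):
        coords = np.zeros((99, 3))
        coords[:, 0] = np.arange(99) * 10.0
        dm = distance_matrix(coords, beads_per_bin=33)
        assert dm.shape == (3, 3)
        assert np.isclose(dm[0, 1], 330.0)
        assert np.isclose(dm[0, 2], 2 * dm[0, 1])

    def test_single_bin(self):
        dm = distance_matrix(np.random.default_rng(0).normal(size=(20, 3)),
                             beads_per_bin=33)
        assert dm.shape == (1, 1) and dm[0, 0] == 0.0

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(100, 3))
        dm = distance_matrix(coords, beads_per_bin=10)
        means = np.array([coords[i * 10:(i + 1) * 10].mean(axis=0)
                          for i in range(10)])
        brute = np.linalg.norm(means[:, None] - means[None, :], axis=2)
        assert np.allclose(dm, brute)


class TestKendall:
    def test_perfect_anticorrelation(self):
        n = 8
        counts = np.zeros((n, n))
        dist = np.zeros((n, n))
        rng = np.random.default_rng(3)
        iu = np.triu_indices(n, 1)
        c = rng.permutation(len(iu[0])) + 1.0
        counts[iu] = c
        dist[iu] = 1.0 / c  # strictly decreasing in counts
        counts += counts.T
        dist += dist.T
        out = kendall_vs_hic(dist, counts, min_separations=[1])
        assert np.isclose(out.tau.iloc[0], -1.0)

    def test_identical_matrices_tau_one(self):
        rng = np.random.default_rng(4)
        m = rng.random((7, 7))
        m = (m + m.T) / 2
        out = kendall_vs_hic(m, m, min_separations=[1])
        assert np.isclose(out.tau.iloc[0], 1.0)

    def test_matches_scipy_pair_counting(self):
        rng = np.random.default_rng(5)
        d = rng.random((6, 6))
        h = rng.integers(0, 5, (6, 6)).astype(float)
        d, h = (d + d.T) / 2, (h + h.T) / 2
        out = kendall_vs_hic(d, h, min_separations=[1], min_pairs=5)
        iu = np.triu_indices(6, 1)
        expect = stats.kendalltau(d[iu], h[iu]).statistic
        assert np.isclose(out.tau.iloc[0], expect)

    def test_too_few_pairs_flagged(self):
        m = np.zeros((4, 4))
        out = kendall_vs_hic(m, m, min_separations=[3], min_pairs=10)
        assert not out.ok.iloc[0] and np.isnan(out.tau.iloc[0])


class TestRadialProfiles:
    def test_feature_confined_to_inner_shell(self):
        rng = np.random.default_rng(6)
        n = 500
        coords = rng.normal(size=(n, 3))
        coords /= np.linalg.norm(coords, axis=1, keepdims=True)
        r = np.full(n, 2000.0)
        r[:50] = 100.0  # feature beads well inside shell 1
        coords *= r[:, None]
        flags = {"feat": np.arange(n) < 50}
        prof, _ = radial_profiles([coords], flags, nucleus_radius=4800.0)
        inner = prof.iloc[0]
        assert inner["feat"] == 100.0 * 50 / (prof.iloc[0].n_beads)
        assert (prof.iloc[1:]["feat"].fillna(0.0) <= 1e-12).iloc[1:].all()

    def test_ubiquitous_feature_100pct(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=1000.0, size=(300, 3))
        prof, _ = radial_profiles([coords], {"all": np.ones(300, bool)},
                                  nucleus_radius=4800.0)
        nonempty = prof[~prof.is_empty]
        assert np.allclose(nonempty["all"], 100.0)

    def test_replicate_std(self):
        c1 = np.zeros((10, 3))
        c2 = np.zeros((10, 3))
        c1[:, 0], c2[:, 0] = 100.0, 300.0
        _, stats_df = radial_profiles([c1, c2], {}, nucleus_radius=4800.0)
        assert np.allclose(stats_df.radial_mean_nm, 200.0)
        assert np.allclose(stats_df.radial_std_nm, 100.0)

    def test_shell_thickness(self):
        prof, _ = radial_profiles([np.zeros((5, 3))], {},
                                  nucleus_radius=4800.0, n_shells=15)
        width = prof.r_hi_nm - prof.r_lo_nm
        assert np.allclose(width, 320.0)


def _dp_bruteforce(delta, k):
    """Exhaustive optimum over all contiguous partitions into k blocks."""
    n = delta.shape[0]
    best = (np.inf, None)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0] + list(cuts) + [n]
        tot = 0.0
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            tot += delta[b0:b1, b0:b1].sum(axis=0).min()
        if tot < best[0] - 1e-12:
            best = (tot, [0] + list(cuts))
    return best


class TestMacrodomains:
    def test_two_block_matrix_recovered(self):
        n = 12
        d = np.full((n, n), 1500.0)
        d[:5, :5] = 100.0
        d[5:, 5:] = 100.0
        np.fill_diagonal(d, 0.0)
        part = macrodomain_partition(d, 2)
        assert part.boundaries == [0, 5]

    def test_single_domain(self):
        d = np.random.default_rng(8).random((6, 6)) * 100
        part = macrodomain_partition((d + d.T) / 2, 1)
        assert part.boundaries == [0]

    @pytest.mark.parametrize("n,k", [(8, 3), (10, 3), (12, 4), (15, 5)])
    def test_equals_bruteforce_optimum(self, n, k):
        rng = np.random.default_rng(100 + n + k)
        d = rng.random((n, n)) * 1200
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        part = macrodomain_partition(d, k)
        delta = dissimilarity_from_distances(d)
        obj = partition_objective(delta, part)
        brute, _ = _dp_bruteforce(delta, k)
        assert np.isclose(obj, brute)

    def test_too_many_domains_rejected(self):
        from chromosteer.errors import RangeError
        with pytest.raises(RangeError):
            macrodomain_partition(np.zeros((3, 3)), 4)

    def test_dissimilarity_rule_literal(self):
        d = np.array([[0.0, 500.0], [800.0, 0.0]])
        delta = dissimilarity_from_distances(d)
        assert delta[0, 1] == 500.0 and delta[1, 0] == 1000.0


class TestOverlap:
    def _part(self, bounds, n):
        return Partition("arm", bounds, n)

    def test_identical_partitions_full_overlap(self):
        a = self._part([0, 3, 7], 10)
        assert partition_overlap(a, a) == 1.0

    def test_hand_counted_overlap(self):
        # labels AAABB vs AABBB: 4 of 5 agree
        a = self._part([0, 3], 5)
        b = self._part([0, 2], 5)
        assert partition_overlap(a, b) == 0.8

    def test_centromere_exclusion(self):
        a = self._part([0, 3], 5)
        b = self._part([0, 2], 5)
        # excluding the disagreeing segment gives perfect overlap
        assert partition_overlap(a, b, exclude=np.array(
            [False, False, True, False, False])) == 1.0

    def test_identical_nontrivial_partition_significant(self):
        a = self._part([0, 7, 13, 25, 31], 40)
        q, p = overlap_significance(a, a, n_random=1000, seed=0)
        assert q == 1.0 and p <= 0.05

    def test_pvalues_superuniform_under_null(self):
        rng = np.random.default_rng(9)
        n_seg, k = 30, 4
        pvals = []
        for rep in range(500):
            pa = random_partition(n_seg, k, rng)
            pb = random_partition(n_seg, k, rng)
            _, p = overlap_significance(pa, pb, n_random=60,
                                        seed=1000 + rep)
            pvals.append(p)
        pvals = np.array(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            # super-uniform: P(p <= t) <= t (+ MC slack)
            assert np.mean(pvals <= t) <= t + 3 * np.sqrt(t * (1 - t) / 500)


class TestProcrustes:
    def test_identical_zero(self):
        a = np.random.default_rng(10).normal(size=(8, 3))
        assert procrustes_rmsd(a, a) < 1e-12

    def test_rigid_invariance(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(20, 3)) * 100
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=3).as_matrix()
        b = a @ rot.T + np.array([10.0, -40.0, 7.0])
        assert procrustes_rmsd(a, b) < 1e-9

    def test_matches_numerical_rotation_search(self):
        # independent oracle: optimize over rotation vectors numerically
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(12)
        a = rng.normal(size=(4, 3)) * 50
        b = rng.normal(size=(4, 3)) * 50
        a0, b0 = a - a.mean(0), b - b.mean(0)

        def cost(rv):
            r = Rotation.from_rotvec(rv).as_matrix()
            return np.sqrt(((a0 - b0 @ r.T) ** 2).sum() / len(a))

        best = min(
            (minimize(cost, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12}).fun
             for x0 in [np.zeros(3), [3, 0, 0], [0, 3, 0], [0, 0, 3],
                        [1.5, 1.5, 1.5]]))
        assert np.isclose(procrustes_rmsd(a, b), best, atol=1e-6)

    def test_too_few_points_rejected(self):
        from chromosteer.errors import FormatError
        with pytest.raises(FormatError):
            procrustes_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestMDS:
    def test_selfconsistency_collinear(self):
        pts = np.zeros((10, 3))
        pts[:, 0] = np.arange(10) * 2.0
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        with np.errstate(divide="ignore"):
            counts = np.where(d > 0, 1.0 / d, 0.0)
        rec = mds_reconstruct(counts, alpha=1.0)
        assert procrustes_rmsd(pts, rec) < 1e-6

    def test_uniform_matrix_gives_simplex(self):
        n = 4
        counts = np.ones((n, n)) - np.eye(n)
        rec = mds_reconstruct(counts)
        pd_ = np.linalg.norm(rec[:, None] - rec[None, :], axis=2)
        off = pd_[np.triu_indices(n, 1)]
        assert np.allclose(off, off[0], atol=1e-6)

    def test_triangle_inequality_after_completion(self):
        rng = np.random.default_rng(13)
        counts = rng.random((8, 8))
        counts = (counts + counts.T) * (rng.random((8, 8)) > 0.5)
        counts = np.triu(counts, 1) + np.triu(counts, 1).T
        # ensure connectivity via a chain
        for i in range(7):
            counts[i, i + 1] = max(counts[i, i + 1], 0.2)
            counts[i + 1, i] = counts[i, i + 1]
        from scipy.sparse import csr_array
        from scipy.sparse.csgraph import shortest_path
        with np.errstate(divide="ignore"):
            d = np.where(counts > 0, counts ** -1.0, 0.0)
        full = shortest_path(csr_array(d), method="FW", directed=False)
        for i, j, k in itertools.permutations(range(8), 3):
            assert full[i, j] <= full[i, k] + full[k, j] + 1e-9

    def test_disconnected_rejected(self):
        from chromosteer.errors import DegenerateDataError
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 1.0
        counts[2, 3] = counts[3, 2] = 1.0
        with pytest.raises(DegenerateDataError):
            mds_reconstruct(counts)
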