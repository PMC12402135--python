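import numpy as np
import pytest

from corticosub import convergence_stats as cv
from corticosub.core_io import BinaryGraph, Parcellation


def _graph_from_targets(targets):
    """Build a convergence graph from {cortical: set(subcortical)}."""
    cort = sorted(targets)
    subs = sorted({s for ts in targets.values() for s in ts})
    n = len(cort) + len(subs)
    A = np.zeros((n, n), dtype=np.int8)
    for ci, c in enumerate(cort):
        for s in targets[c]:
            si = len(cort) + subs.index(s)
            A[ci, si] = A[si, ci] = 1
    return BinaryGraph(adjacency=A, directed=False,
                       labels=cort + subs,
                       subsets={"cortical": np.arange(len(cort)),
                                "subcortical": np.arange(len(cort), n)})


class TestBidirectionalGraph:
    def test_and_rule(self):
        C = np.zeros((4, 4), dtype=int)
        C[0, 2] = 1  # one-directional: dropped
        C[1, 3] = C[3, 1] = 1  # bidirectional: kept
        g = cv.bidirectional_graph(C, np.array([0, 1]), np.array([2, 3]))
        assert g.adjacency[0, 2] == 0
        assert g.adjacency[1, 3] == g.adjacency[3, 1] == 1

    def test_symmetric_input_equals_or_rule(self, rng):
        C = (rng.random((6, 6)) < 0.4).astype(int)
        C = C | C.T
        np.fill_diagonal(C, 0)
        cort, sub = np.arange(3), np.arange(3, 6)
        g = cv.bidirectional_graph(C, cort, sub)
        expected = np.zeros_like(C)
        expected[np.ix_(cort, sub)] = C[np.ix_(cort, sub)]
        expected[np.ix_(sub, cort)] = C[np.ix_(sub, cort)]
        np.testing.assert_array_equal(g.adjacency, expected)

    def test_matches_elementwise_and_oracle(self, rng):
        C = (rng.random((8, 8)) < 0.5).astype(int)
        np.fill_diagonal(C, 0)
        cort, sub = np.arange(5), np.arange(5, 8)
        g = cv.bidirectional_graph(C, cort, sub)
        for r in cort:
            for s in sub:
                assert g.adjacency[r, s] == (C[r, s] and C[s, r])
        # no cortico-cortical / subcortico-subcortical edges survive
        assert g.adjacency[np.ix_(cort, cort)].sum() == 0
        assert g.adjacency[np.ix_(sub, sub)].sum() == 0

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            cv.bidirectional_graph(np.zeros((3, 3)), np.array([0, 1]),
                                   np.array([1, 2]))


class TestCounts:
    def test_fixture_counts(self, table1):
        parcellation, graph = table1
        counts = cv.convergence_counts(graph)
        assert counts["THA-VA2"] == 0
        assert counts["GPL-p"] == 0
        assert counts["AMY-m"] == 16
        assert counts.max() == 16

    def test_empty_graph_all_zero(self):
        g = BinaryGraph(adjacency=np.zeros((5, 5), dtype=np.int8),
                        subsets={"cortical": np.arange(3),
                                 "subcortical": np.array([3, 4])})
        assert cv.convergence_counts(g).sum() == 0


class TestProportionConvergence:
    def test_worked_example(self):
        # c1,c2 -> {s1,s2}; c3 -> {s1}: raw shared-target counts are
        # (c1,c2)=2, (c1,c3)=1, (c2,c3)=1 so O = 0.5, 0.25, 0.25
        g = _graph_from_targets({"c1": {"s1", "s2"}, "c2": {"s1", "s2"},
                                 "c3": {"s1"}})
        O = cv.proportion_convergence(g)
        assert O[0, 1] == pytest.approx(0.5)
        assert O[0, 2] == pytest.approx(0.25)
        assert O[1, 2] == pytest.approx(0.25)

    def test_node_without_targets_shares_nothing(self):
        g = _graph_from_targets({"c1": {"s1"}, "c2": {"s1"}, "c3": set()})
        O = cv.proportion_convergence(g)
        assert O[2].sum() == 0

    def test_fixture_normalization(self, table1):
        _, graph = table1
        O = cv.proportion_convergence(graph)
        iu = np.triu_indices(O.shape[0], 1)
        assert O[iu].sum() == pytest.approx(1.0)
        assert (O >= 0).all() and (O <= 1).all()

    def test_empty_warns(self):
        g = _graph_from_targets({"c1": {"s1"}, "c2": {"s2"}})
        with pytest.warns(RuntimeWarning, match="shares"):
            O = cv.proportion_convergence(g)
        assert O.sum() == 0


class TestDistances:
    def _parc(self, centroids, labels=None):
        n = len(centroids)
        return Parcellation(
            labels=labels or [f"c{i}" for i in range(n)],
            roi_class=["cortical"] * n, rsn=["VIS"] * n,
            centroids=centroids, voxel_counts=np.ones(n, dtype=int))

    def test_identical_roi_distance_zero(self):
        p = self._parc([[(-5, 0, 0), (5, 0, 0)]] * 2, labels=["a", "b"])
        assert cv.roi_distance(p, 0, 1) == 0.0

    def test_hand_computed_bilateral(self):
        # hemisphere-matched distances, averaged
        c1 = [(-5, -88, 2), (8, -92, -2)]
        c2 = [(-4, -25, 56), (4, -25, 58)]
        p = self._parc([c1, c2])
        left = np.linalg.norm(np.subtract(c1[0], c2[0]))
        right = np.linalg.norm(np.subtract(c1[1], c2[1]))
        assert cv.roi_distance(p, 0, 1) == pytest.approx((left + right) / 2)

    def test_medial_mixing_averages_all_combinations(self):
        c1 = [(2, -54, -8)]
        c2 = [(-4, 28, 47), (5, 28, 48)]
        p = self._parc([c1, c2])
        expect = np.mean([np.linalg.norm(np.subtract(c1[0], c2[k]))
                          for k in range(2)])
        assert cv.roi_distance(p, 0, 1) == pytest.approx(expect)

    def test_translation_invariance(self, rng):
        cents = [[tuple(rng.normal(0, 30, 3)), tuple(rng.normal(0, 30, 3))]
                 for _ in range(4)]
        p1 = self._parc(cents)
        shift = np.array([10.0, -3.0, 7.0])
        p2 = self._parc([[tuple(np.add(c, shift)) for c in cc] for cc in cents])
        for i in range(4):
            for j in range(i + 1, 4):
                assert cv.roi_distance(p1, i, j) == pytest.approx(
                    cv.roi_distance(p2, i, j))

    def test_missing_centroid_rejected(self, table1):
        parcellation, _ = table1
        with pytest.raises(ValueError, match="missing centroid"):
            cv.roi_distance(parcellation, 0, 30)  # subcortical ROI: NaN

    def test_matrix_symmetry_and_triangle_inequality(self, rng):
        cents = [[tuple(rng.normal(0, 40, 3)), tuple(rng.normal(0, 40, 3))]
                 for _ in range(6)]
        D = cv.pair_distance_matrix(self._parc(cents), np.arange(6))
        np.testing.assert_allclose(D, D.T)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestDistributions:
    def test_single_bin_holds_all_weight(self):
        O = np.array([[0, 0.6, 0.4], [0.6, 0, 0], [0.4, 0, 0]])
        D = np.full((3, 3), 3.0)
        np.fill_diagonal(D, 0)
        dist = cv.fs_fd_distributions(O, D, ["VIS", "VIS", "DMN"],
                                      fit="moments")
        assert dist.n_bins == 1
        assert dist.fs_binned[0] == pytest.approx(0.6)
        assert dist.fd_binned[0] == pytest.approx(0.4)

    def test_classes_partition_weighted_pairs(self, table1):
        parcellation, graph = table1
        O = cv.proportion_convergence(graph)
        cort = graph.subsets["cortical"]
        D = cv.pair_distance_matrix(parcellation, cort)
        rsn = [parcellation.rsn[i] for i in cort]
        dist = cv.fs_fd_distributions(O, D, rsn)
        assert dist.fs_binned.sum() + dist.fd_binned.sum() == pytest.approx(1.0)

    def test_moment_estimator_consistency(self, rng):
        # pair distances ~ N(50, 10^2), uniform weights: recovered mu/sigma
        n = 40
        D = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        D[iu] = np.abs(rng.normal(50, 10, iu[0].size))
        D = D + D.T
        O = np.zeros((n, n))
        O[iu] = 1.0 / iu[0].size
        O = O + O.T
        with pytest.warns(RuntimeWarning, match="FD"):  # single-class input
            dist = cv.fs_fd_distributions(O, D, ["VIS"] * n, fit="moments")
        fit = dist.fits["FS"]
        assert fit["mu"] == pytest.approx(50, abs=2)
        assert fit["sigma"] == pytest.approx(10, abs=1.5)

    def test_lsq_recovers_gaussian_histogram(self):
        # construct pair weights that sample an exact normal density
        n = 60
        rng = np.random.default_rng(1)
        iu = np.triu_indices(n, 1)
        d = rng.uniform(0, 120, iu[0].size)
        w = np.exp(-((d - 60) ** 2) / (2 * 15 ** 2))
        w /= w.sum()
        D = np.zeros((n, n)); D[iu] = d; D += D.T
        O = np.zeros((n, n)); O[iu] = w; O += O.T
        with pytest.warns(RuntimeWarning, match="FD"):  # single-class input
            dist = cv.fs_fd_distributions(O, D, ["VIS"] * n, fit="lsq")
        fit = dist.fits["FS"]
        assert fit["mu"] == pytest.approx(60, abs=5)
        assert fit["sigma"] == pytest.approx(15, abs=4)

    def test_span_must_cover_observed_max(self):
        O = np.array([[0, 1.0], [1.0, 0]])
        D = np.array([[0, 50.0], [50.0, 0]])
        with pytest.raises(ValueError, match="span"):
            cv.fs_fd_distributions(O, D, ["VIS", "VIS"], span=40)

    def test_empty_class_warns(self):
        O = np.array([[0, 1.0], [1.0, 0]])
        D = np.array([[0, 12.0], [12.0, 0]])
        with pytest.warns(RuntimeWarning, match="FD"):
            dist = cv.fs_fd_distributions(O, D, ["VIS", "VIS"], fit="moments")
        assert "FD" not in dist.fits


class TestPairedTest:
    def test_identical_vectors_zero(self):
        t, dof, p = cv.fs_fd_paired_test(np.ones(5), np.ones(5))
        assert t == 0.0 and dof == 4 and p == 1.0

    def test_constant_offset_gives_infinite_sentinel(self):
        fs = np.linspace(0, 1, 6)
        t, dof, p = cv.fs_fd_paired_test(fs, fs + 0.01)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_textbook_formula(self, rng):
        fs = rng.random(10)
        fd = rng.random(10)
        t, dof, p = cv.fs_fd_paired_test(fs, fd)
        diff = fd - fs
        t_expect = diff.mean() / (diff.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_expect, abs=1e-10)
        assert dof == 9

    def test_minimum_bins(self):
        with pytest.raises(ValueError, match="bins"):
            cv.fs_fd_paired_test(np.ones(1), np.ones(1))


class TestNetworkLevel:
    def test_fixture_percentages(self, table1):
        parcellation, graph = table1
        table = cv.network_level_convergence(graph, parcellation)
        assert table.loc["THA", "primary_pct"] == pytest.approx(80.0)
        assert table.loc["BGN", "primary_pct"] == pytest.approx(40.0)
        assert table.loc["SLN", "association_pct"] == pytest.approx(100 * 59 / 73)
        assert round(table.loc["SLN", "association_pct"]) == 81

    def test_all_primary_connections(self):
        g = _graph_from_targets({"c1": {"s1"}, "c2": {"s1"}})
        parc = Parcellation(
            labels=["c1", "c2", "s1"],
            roi_class=["cortical", "cerebellar", "subcortical"],
            rsn=["VIS", "CER", "THA"],
            centroids=[[(0, 0, 0)]] * 3, voxel_counts=[1, 1, 1])
        table = cv.network_level_convergence(g, parc)
        assert table.loc["THA", "primary_pct"] == 100.0
        assert table.loc["THA", "association_pct"] == 0.0

    def test_percentages_sum_to_100_where_connected(self, table1):
        parcellation, graph = table1
        table = cv.network_level_convergence(graph, parcellation)
        for _, row in table.iterrows():
            if row["primary_count"] + row["association_count"] > 0:
                assert row["primary_pct"] + row["association_pct"] == pytest.approx(100.0)
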