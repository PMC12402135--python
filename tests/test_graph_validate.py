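import numpy as np
import pytest

from corticosub import graph_validate as gv
from corticosub.core_io import Parcellation
from conftest import bfs_distances, modularity_bruteforce


def random_graph(rng, n=12, p=0.35):
    A = (rng.random((n, n)) < p).astype(int)
    A = ((A + A.T) > 0).astype(int)
    np.fill_diagonal(A, 0)
    return A


class TestSymmetrize:
    def test_or_and_rules(self):
        C = np.array([[0, 1, 0], [0, 0, 1], [0, 1, 0]])
        np.testing.assert_array_equal(
            gv.symmetrize(C, "or"), [[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        np.testing.assert_array_equal(
            gv.symmetrize(C, "and"), [[0, 0, 0], [0, 0, 1], [0, 1, 0]])


class TestNodeMetricsOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_against_edge_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        A = random_graph(rng)
        partition = rng.integers(0, 3, size=12)
        frame = gv.node_degree_metrics(A, partition)
        for i in range(12):
            nbrs = np.flatnonzero(A[i])
            assert frame["degree"].iloc[i] == len(nbrs)
            wmd = sum(1 for j in nbrs if partition[j] == partition[i])
            assert frame["wmd"].iloc[i] == wmd
            # participation by explicit summation
            if len(nbrs):
                frac = [sum(1 for j in nbrs if partition[j] == c) / len(nbrs)
                        for c in np.unique(partition)]
                assert frame["participation"].iloc[i] == pytest.approx(
                    1 - sum(f ** 2 for f in frac), abs=1e-12)
            # clustering by triangle counting
            if len(nbrs) >= 2:
                links = sum(A[u, v] for k, u in enumerate(nbrs)
                            for v in nbrs[k + 1:])
                expect = 2 * links / (len(nbrs) * (len(nbrs) - 1))
                assert frame["clustering"].iloc[i] == pytest.approx(expect)
            else:
                assert frame["clustering"].iloc[i] == 0
        # z-score reconstruction per module
        for c in np.unique(partition):
            members = partition == c
            w = frame["wmd"].to_numpy()[members].astype(float)
            sd = w.std()
            expect = np.zeros_like(w) if sd == 0 else (w - w.mean()) / sd
            np.testing.assert_allclose(frame["wmd_z"].to_numpy()[members], expect)

    def test_wmd_sums_to_degree_across_modules(self, rng):
        A = random_graph(rng)
        partition = rng.integers(0, 4, size=12)
        k = A.sum(axis=1)
        total = np.zeros(12)
        for c in np.unique(partition):
            onehot = partition == c
            total += A[:, onehot].sum(axis=1)
        np.testing.assert_array_equal(total, k)

    def test_isolated_node_conventions(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = 1
        frame = gv.node_degree_metrics(A, np.array([0, 0, 1]))
        assert frame.loc[2, "degree"] == 0
        assert frame.loc[2, "participation"] == 0.0
        assert frame.loc[2, "wmd_z"] == 0.0

    def test_density_requires_parcellation(self, rng):
        A = random_graph(rng, n=3)
        parc = Parcellation(labels=["a", "b", "c"],
                            roi_class=["subcortical"] * 3,
                            rsn=["THA"] * 3,
                            centroids=[[(0, 0, 0)]] * 3,
                            voxel_counts=[10, 20, 40])
        frame = gv.node_degree_metrics(A, np.zeros(3, dtype=int), parc)
        np.testing.assert_allclose(frame["density"],
                                   A.sum(axis=1) / np.array([10, 20, 40]))


class TestParticipation:
    def test_closed_forms(self):
        # k=4 split 2/2 over two communities -> 0.5
        A = np.zeros((5, 5), dtype=int)
        A[0, 1:] = A[1:, 0] = 1
        part = np.array([0, 0, 0, 1, 1])
        assert gv.participation(A, part)[0] == pytest.approx(0.5)
        # k=3 split 1/1/1 over three -> 2/3
        A = np.zeros((4, 4), dtype=int)
        A[0, 1:] = A[1:, 0] = 1
        part = np.array([0, 0, 1, 2])
        assert gv.participation(A, part)[0] == pytest.approx(2 / 3)

    def test_fully_within_community_is_zero(self):
        A = np.ones((4, 4), dtype=int)
        np.fill_diagonal(A, 0)
        np.testing.assert_allclose(gv.participation(A, np.zeros(4, dtype=int)), 0)


class TestModularity:
    def test_two_cliques_half(self):
        A = np.zeros((8, 8), dtype=int)
        A[:4, :4] = 1
        A[4:, 4:] = 1
        np.fill_diagonal(A, 0)
        assert gv.modularity_q(A, np.repeat([0, 1], 4)) == pytest.approx(0.5)

    def test_single_community_zero(self, rng):
        A = random_graph(rng)
        assert gv.modularity_q(A, np.zeros(12, dtype=int)) == pytest.approx(0.0)

    def test_random_partition_near_zero(self):
        rng = np.random.default_rng(0)
        qs = []
        for _ in range(20):
            A = random_graph(rng, n=200, p=0.05)
            qs.append(gv.modularity_q(A, rng.integers(0, 4, 200)))
        assert abs(np.mean(qs)) < 0.05

    def test_matches_bruteforce(self, rng):
        A = random_graph(rng)
        part = rng.integers(0, 3, 12)
        assert gv.modularity_q(A, part) == pytest.approx(
            modularity_bruteforce(A, part), abs=1e-10)


class TestPathLength:
    def test_complete_graph(self):
        A = np.ones((5, 5), dtype=int)
        np.fill_diagonal(A, 0)
        assert gv.characteristic_path_length(A) == 1.0

    def test_star(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1:] = A[1:, 0] = 1
        assert gv.characteristic_path_length(A) == pytest.approx(1.5)

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            A = random_graph(rng, n=15, p=0.3)
            D = bfs_distances(A)
            if np.isinf(D).any():
                continue
            mask = ~np.eye(15, dtype=bool)
            assert gv.characteristic_path_length(A) == pytest.approx(
                D[mask].mean())

    def test_disconnected_handling(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = 1
        with pytest.raises(ValueError, match="disconnected"):
            gv.characteristic_path_length(A)
        assert gv.characteristic_path_length(A, largest_component=True) == 1.0


class TestRewiring:
    def test_degree_sequence_preserved(self, rng):
        A = random_graph(rng)
        ens = gv.rewire_null_ensemble(A, n=20, seed=0)
        deg = A.sum(axis=1)
        for g in ens.graphs:
            np.testing.assert_array_equal(g.sum(axis=1), deg)
            assert g.sum() == A.sum()

    def test_deterministic(self, rng):
        A = random_graph(rng)
        e1 = gv.rewire_null_ensemble(A, n=5, seed=7)
        e2 = gv.rewire_null_ensemble(A, n=5, seed=7)
        for g1, g2 in zip(e1.graphs, e2.graphs):
            np.testing.assert_array_equal(g1, g2)

    def test_lattice_nulls_lose_clustering(self):
        # ring lattice with k=4 neighbours: rewired nulls have lower
        # clustering on average (small-world contrast)
        n = 24
        A = np.zeros((n, n), dtype=int)
        for i in range(n):
            for d in (1, 2):
                A[i, (i + d) % n] = A[(i + d) % n, i] = 1
        import networkx as nx
        c_real = nx.average_clustering(nx.from_numpy_array(A))
        ens = gv.rewire_null_ensemble(A, n=20, seed=1)
        c_null = np.mean([nx.average_clustering(nx.from_numpy_array(g))
                          for g in ens.graphs])
        assert c_null < c_real

    def test_too_few_edges_rejected(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = A[1, 0] = 1
        with pytest.raises(ValueError, match="2 edges"):
            gv.rewire_null_ensemble(A)


class TestNullComparison:
    def test_real_equal_to_null_mean_not_significant(self, rng):
        nulls = rng.standard_normal(1000)
        table = gv.null_comparison({"m": nulls.mean()}, {"m": nulls})
        row = table.iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-10)
        assert not row["significant"]
        assert row["dof"] == 999

    def test_planted_modularity_detected(self, rng):
        A = np.zeros((12, 12), dtype=int)
        A[:6, :6] = 1
        A[6:, 6:] = 1
        np.fill_diagonal(A, 0)
        part = np.repeat([0, 1], 6)
        ens = gv.rewire_null_ensemble(A, n=100, seed=0)
        null_q = ens.metric(lambda g: gv.modularity_q(g, part))
        table = gv.null_comparison({"Q": gv.modularity_q(A, part)},
                                   {"Q": null_q})
        row = table.iloc[0]
        assert row["significant"] and row["direction"] == "above"

    def test_zero_variance_null_fallback(self):
        nulls = np.full(10, 2.0)
        table = gv.null_comparison({"m": 2.0, "m2": 3.0},
                                   {"m": nulls, "m2": nulls})
        assert table.iloc[0]["t"] == 0.0
        assert np.isinf(table.iloc[1]["t"])


class TestClassifyAndCompare:
    @pytest.mark.parametrize("p,z,expected", [
        (0.6, 1.2, "connector hub"),
        (0.5, 0.0, "non-hub"),
        (0.7, -0.5, "non-hub connector"),
        (0.2, 2.0, "provincial hub"),
    ])
    def test_rules(self, p, z, expected):
        labels, _ = gv.classify_nodes(np.array([p]), np.array([z]))
        assert labels[0] == expected

    def test_percentages(self, rng):
        p = np.where(np.arange(27) < 22, 0.7, 0.3)
        z = np.ones(27)
        _, pct = gv.classify_nodes(p, z)
        assert pct["connector"] == pytest.approx(100 * 22 / 27)

    def test_compare_groups(self, rng):
        import pandas as pd
        a = pd.DataFrame({"x": rng.normal(0, 1, 50)})
        b = pd.DataFrame({"x": rng.normal(2, 1, 50)})
        table = gv.compare_groups(a, b)
        row = table.iloc[0]
        assert row["significant"]
        assert row["dof"] == 98
        same = gv.compare_groups(a, a).iloc[0]
        assert same["t"] == 0.0
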