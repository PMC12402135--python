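import numpy as np
import pytest

from corticosub import core_io, synthetic_data


@pytest.fixture(scope="session")
def table1():
    """Packaged convergence-table fixture: (parcellation, bipartite graph)."""
    return core_io.load_table1_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_panel():
    """A small dependent panel shared by connectivity tests: 2 subjects x
    2 sessions, 8 ROIs in two planted communities."""
    spec = synthetic_data.SimulationSpec(
        community_assignment=np.repeat([0, 1], 4),
        n_subjects=2, n_sessions=2, n_timepoints=260,
        rho_within=0.5, rho_between=0.0, ar_coefficient=0.3, seed=11)
    return synthetic_data.simulate_panel(spec)


def modularity_bruteforce(W, partition, gamma=1.0):
    """Independent double-loop evaluation of the modularity formula."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for i in range(n):
        for j in range(n):
            if partition[i] == partition[j]:
                q += W[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def bfs_distances(adj):
    """All-pairs shortest paths by explicit breadth-first search."""
    A = np.asarray(adj) != 0
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        frontier = [s]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(A[u]):
                    if D[s, v] == np.inf:
                        D[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return D
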