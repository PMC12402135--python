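"""Graph-theoretic metrics, degree-preserving null models and hub typology.

All metrics operate on an undirected unit-edge graph. The group binary
connectivity matrix is directed, so callers symmetrize first: the default
rule keeps an undirected edge when either direction is significant ("or");
the stricter "and" rule (both directions) is the convention the convergence
analysis mandates and is available behind the same flag.

Conventions for degenerate cases: a module whose nodes all share the same
within-module degree gets z = 0; an isolated node gets participation 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from .community_detect import modularity_value
from .core_io import Parcellation

__all__ = [
    "NullEnsemble",
    "symmetrize",
    "node_degree_metrics",
    "participation",
    "modularity_q",
    "characteristic_path_length",
    "rewire_null_ensemble",
    "null_comparison",
    "classify_nodes",
    "compare_groups",
]

NODE_TYPES = ("connector hub", "non-hub connector", "provincial hub", "non-hub")


def symmetrize(adjacency: np.ndarray, mode: str = "or") -> np.ndarray:
    """Undirected 0/1 adjacency from a directed one.

    ``or``: edge iff either direction present; ``and``: edge iff both.
    """
    A = (np.asarray(adjacency) != 0).astype(np.int8)
    if mode == "or":
        S = A | A.T
    elif mode == "and":
        S = A & A.T
    else:
        raise ValueError("mode must be 'or' or 'and'")
    np.fill_diagonal(S, 0)
    return S


def _undirected(adjacency: np.ndarray, mode: str) -> np.ndarray:
    A = np.asarray(adjacency)
    if np.array_equal(A, A.T):
        return (A != 0).astype(np.int8)
    return symmetrize(A, mode)


def participation(binary: np.ndarray, partition: np.ndarray,
                  symmetrize_mode: str = "or") -> np.ndarray:
    """P_i = 1 - sum_m (k_im / k_i)^2 over all communities m; 0 if k_i = 0."""
    A = _undirected(binary, symmetrize_mode)
    partition = np.asarray(partition)
    k = A.sum(axis=1)
    comms = np.unique(partition)
    onehot = (partition[None, :] == comms[:, None]).astype(float)
    kim = A @ onehot.T  # node x community
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = kim / k[:, None]
    p = 1.0 - np.nansum(frac ** 2, axis=1)
    p[k == 0] = 0.0
    return p


def node_degree_metrics(binary: np.ndarray, partition: np.ndarray,
                        parcellation: Parcellation | None = None,
                        labels: list[str] | None = None,
                        symmetrize_mode: str = "or") -> pd.DataFrame:
    """Degree, within-module degree (+ z), participation, clustering and,
    when a parcellation supplies voxel counts, connection density
    (degree / voxels). Rows are nodes."""
    A = _undirected(binary, symmetrize_mode)
    partition = np.asarray(partition)
    if partition.size != A.shape[0]:
        raise ValueError("partition must cover all nodes")
    n = A.shape[0]
    k = A.sum(axis=1)
    wmd = np.array([A[i, partition == partition[i]].sum() for i in range(n)])
    z = np.zeros(n, dtype=float)
    for c in np.unique(partition):
        members = partition == c
        mu, sd = wmd[members].mean(), wmd[members].std(ddof=0)
        if sd > 0:
            z[members] = (wmd[members] - mu) / sd
    clustering = np.array([
        nx.clustering(nx.from_numpy_array(A), i) for i in range(n)])
    frame = pd.DataFrame({
        "degree": k,
        "wmd": wmd,
        "wmd_z": z,
        "participation": participation(A, partition),
        "clustering": clustering,
    })
    if parcellation is not None:
        if parcellation.n != n:
            raise ValueError("parcellation does not match graph size")
        frame["density"] = k / parcellation.voxel_counts
        frame.index = pd.Index(parcellation.labels, name="roi")
    elif labels is not None:
        frame.index = pd.Index(labels, name="roi")
    return frame


def modularity_q(binary: np.ndarray, partition: np.ndarray, gamma: float = 1.0,
                 symmetrize_mode: str = "or") -> float:
    """Newman-Girvan modularity of the given partition on the undirected
    graph."""
    return modularity_value(_undirected(binary, symmetrize_mode).astype(float),
                            partition, gamma)


def characteristic_path_length(binary: np.ndarray,
                               largest_component: bool = False,
                               symmetrize_mode: str = "or") -> float:
    """Mean shortest-path length over all node pairs (unit edges).

    Raises on a disconnected graph unless ``largest_component`` restricts
    the computation to the largest connected component.
    """
    A = _undirected(binary, symmetrize_mode)
    D = shortest_path(A, method="D", directed=False, unweighted=True)
    if np.isinf(D).any():
        if not largest_component:
            raise ValueError(
                "graph is disconnected; pass largest_component=True to "
                "restrict to the largest connected component")
        G = nx.from_numpy_array(A)
        comp = max(nx.connected_components(G), key=len)
        idx = sorted(comp)
        D = D[np.ix_(idx, idx)]
    n = D.shape[0]
    if n < 2:
        raise ValueError("path length undefined for fewer than 2 nodes")
    mask = ~np.eye(n, dtype=bool)
    return float(D[mask].mean())


@dataclass
class NullEnsemble:
    """Degree-preserving rewired graphs; every member keeps each node's
    degree exactly."""

    graphs: list[np.ndarray]
    seed: int
    swaps_requested: int
    swaps_done: list[int]

    def __len__(self) -> int:
        return len(self.graphs)

    def metric(self, fn) -> np.ndarray:
        return np.array([fn(g) for g in self.graphs])


def rewire_null_ensemble(binary: np.ndarray, n: int = 1000,
                         swaps_per_edge: int = 10, seed: int = 0,
                         symmetrize_mode: str = "or") -> NullEnsemble:
    """Degree-preserving double-edge-swap null networks."""
    A = _undirected(binary, symmetrize_mode)
    G0 = nx.from_numpy_array(A)
    G0.add_nodes_from(range(A.shape[0]))
    m = G0.number_of_edges()
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    nswap = m * swaps_per_edge
    degrees = A.sum(axis=1)
    graphs, done = [], []
    rng = np.random.default_rng(seed)
    for _ in range(n):
        H = G0.copy()
        member_seed = int(rng.integers(0, 2 ** 31 - 1))
        swapped = nswap
        try:
            nx.double_edge_swap(H, nswap=nswap, max_tries=nswap * 200,
                                seed=member_seed)
        except nx.NetworkXAlgorithmError:
            swapped = -1  # budget exhausted; H holds the swaps made so far
            warnings.warn(
                "graph too constrained: swap budget exhausted before "
                f"{nswap} swaps", RuntimeWarning, stacklevel=2)
        B = nx.to_numpy_array(H, nodelist=range(A.shape[0]), dtype=np.int8)
        assert np.array_equal(B.sum(axis=1), degrees), "degree sequence changed"
        graphs.append(B)
        done.append(int(swapped))
    return NullEnsemble(graphs=graphs, seed=seed,
                        swaps_requested=nswap, swaps_done=done)


def null_comparison(real_values: dict[str, float | np.ndarray],
                    null_values: dict[str, np.ndarray],
                    alpha: float = 0.01,
                    bonferroni: bool = True) -> pd.DataFrame:
    """One-sample t-tests of each null distribution against the real value.

    ``real_values[name]`` may be a scalar (network-level metric) or a vector
    (node-level metric, with ``null_values[name]`` of shape
    (n_null, n_nodes)). A zero-variance null falls back to an exact
    comparison (t = 0 when equal, an infinite sentinel otherwise).
    """
    rows = []
    names = list(real_values)
    n_tests = sum(np.size(real_values[name]) for name in names) if bonferroni else 1
    for name in names:
        real = np.atleast_1d(np.asarray(real_values[name], dtype=float))
        nulls = np.asarray(null_values[name], dtype=float)
        if nulls.ndim == 1:
            nulls = nulls[:, None]
        if nulls.shape[0] < 1:
            raise ValueError("empty null ensemble")
        for j in range(real.size):
            col = nulls[:, j]
            sd = col.std(ddof=1)
            if sd == 0:
                t = 0.0 if col[0] == real[j] else np.inf
                p = 1.0 if t == 0 else 0.0
            else:
                t, p = stats.ttest_1samp(col, popmean=real[j])
            direction = ("above" if real[j] > col.mean()
                         else "below" if real[j] < col.mean() else "equal")
            p_corr = min(1.0, float(p) * n_tests) if bonferroni else float(p)
            rows.append({
                "metric": name, "node": j if real.size > 1 else pd.NA,
                "real": real[j], "null_mean": col.mean(), "null_sd": sd,
                "t": float(np.abs(t)), "dof": col.size - 1,
                "p_corrected": p_corr, "direction": direction,
                "significant": p_corr < alpha,
            })
    return pd.DataFrame(rows)


def classify_nodes(p_coef: np.ndarray, z: np.ndarray,
                   p_threshold: float = 0.5,
                   z_threshold: float = 0.0) -> tuple[np.ndarray, dict[str, float]]:
    """Hub typology from participation and within-module-degree z-score.

    connector hub: P > 0.5 and z > 0; non-hub connector: P > 0.5, z <= 0;
    provincial hub: P <= 0.5, z > 0; non-hub otherwise (boundaries land on
    the non-strict side). Returns per-node labels and class percentages.
    """
    p_coef = np.asarray(p_coef, dtype=float)
    z = np.asarray(z, dtype=float)
    if p_coef.shape != z.shape:
        raise ValueError("P and z must align")
    conn = p_coef > p_threshold
    hub = z > z_threshold
    labels = np.where(conn & hub, NODE_TYPES[0],
             np.where(conn & ~hub, NODE_TYPES[1],
             np.where(~conn & hub, NODE_TYPES[2], NODE_TYPES[3])))
    pct = {t: 100.0 * float((labels == t).sum()) / labels.size for t in NODE_TYPES}
    pct["connector"] = pct[NODE_TYPES[0]] + pct[NODE_TYPES[1]]
    return labels, pct


def compare_groups(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                   alpha: float = 0.01) -> pd.DataFrame:
    """Pooled-variance two-sample t-test per shared metric column."""
    if len(metrics_a) < 2 or len(metrics_b) < 2:
        raise ValueError("each group needs at least 2 members")
    rows = []
    for col in metrics_a.columns.intersection(metrics_b.columns):
        a = metrics_a[col].to_numpy(dtype=float)
        b = metrics_b[col].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "metric": col, "mean_a": a.mean(), "mean_b": b.mean(),
            "sd_a": a.std(ddof=1), "sd_b": b.std(ddof=1),
            "t": float(t), "dof": a.size + b.size - 2, "p": float(p),
            "significant": bool(p < alpha),
        })
    return pd.DataFrame(rows)
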