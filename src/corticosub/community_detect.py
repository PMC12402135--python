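"""Louvain consensus community detection with a resolution sweep.

The workflow mirrors common practice for small functional-connectivity
graphs: many seeded Louvain runs per resolution, a co-assignment agreement
matrix thresholded at tau, Louvain re-run on the thresholded agreement until
the partition stabilizes, and silhouette-based confidence used to pick the
resolution.

Adjacency handling: matrices are symmetrized as (A + A')/2 and negative
weights are clipped to zero before modularity optimization; silhouette
distances are d = 1 - w on the symmetrized normalized weighted matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CommunitySolution",
    "GammaSweepResult",
    "ConsensusError",
    "modularity_value",
    "louvain_once",
    "consensus_partition",
    "silhouette_scores",
    "gamma_sweep",
]


class ConsensusError(RuntimeError):
    pass


@dataclass
class CommunitySolution:
    gamma: float
    partition: np.ndarray
    q_value: float
    agreement: np.ndarray
    silhouettes: np.ndarray | None = None
    confidence: float = np.nan
    matrix_type: str | None = None

    @property
    def n_communities(self) -> int:
        return int(np.unique(self.partition).size)


@dataclass
class GammaSweepResult:
    best: CommunitySolution
    table: pd.DataFrame
    solutions: dict[tuple[float, str], CommunitySolution] = field(default_factory=dict)


def _clean_adjacency(adjacency: np.ndarray) -> np.ndarray:
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if A.shape[0] == 0:
        raise ValueError("empty graph")
    W = (A + A.T) / 2.0
    W = np.clip(W, 0.0, None)
    np.fill_diagonal(W, 0.0)
    return W


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Contiguous integer labels in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        mapping.setdefault(int(lab), len(mapping))
        out[i] = mapping[int(lab)]
    return out


def modularity_value(W: np.ndarray, partition: np.ndarray, gamma: float = 1.0) -> float:
    """Newman-Girvan modularity Q at resolution gamma on a symmetric,
    non-negative weight matrix.

    Q = (1/2m) sum_ij [W_ij - gamma k_i k_j / 2m] delta(c_i, c_j).
    """
    W = np.asarray(W, dtype=float)
    partition = np.asarray(partition)
    k = W.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    same = partition[:, None] == partition[None, :]
    return float(((W - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def _merge_refine(W: np.ndarray, labels: np.ndarray, gamma: float) -> np.ndarray:
    """Greedy community-merge hill climb on Q; cheap for few communities.

    Guarantees that no pairwise community merge can further improve Q — in
    particular, at gamma = 0 all connected components collapse into single
    communities.
    """
    labels = _relabel(labels)
    while True:
        comms = np.unique(labels)
        if comms.size < 2:
            return labels
        k = W.sum(axis=1)
        two_m = k.sum()
        if two_m == 0:
            return labels
        # e[c, d]: total weight between communities; kc[c]: total degree
        onehot = (labels[:, None] == comms[None, :]).astype(float)
        e = onehot.T @ W @ onehot
        kc = onehot.T @ k
        # delta Q for merging c and d: 2 (e_cd - gamma kc_c kc_d / 2m) / 2m
        dq = 2.0 * (e - gamma * np.outer(kc, kc) / two_m) / two_m
        np.fill_diagonal(dq, -np.inf)
        c, d = np.unravel_index(np.argmax(dq), dq.shape)
        if dq[c, d] <= 1e-12:
            return labels
        labels = np.where(labels == comms[d], comms[c], labels)
        labels = _relabel(labels)


def louvain_once(adjacency: np.ndarray, gamma: float = 1.0,
                 seed: int = 0) -> tuple[np.ndarray, float]:
    """One seeded Louvain run plus a community-merge refinement pass."""
    W = _clean_adjacency(adjacency)
    G = nx.from_numpy_array(W)
    G.add_nodes_from(range(W.shape[0]))
    parts = nx.community.louvain_communities(
        G, weight="weight", resolution=gamma, seed=int(seed))
    labels = np.empty(W.shape[0], dtype=int)
    for ci, nodes in enumerate(parts):
        for v in nodes:
            labels[v] = ci
    labels = _merge_refine(W, labels, gamma)
    return labels, modularity_value(W, labels, gamma)


def _agreement(partitions: list[np.ndarray]) -> np.ndarray:
    n = partitions[0].size
    agg = np.zeros((n, n))
    for p in partitions:
        agg += p[:, None] == p[None, :]
    agg /= len(partitions)
    np.fill_diagonal(agg, 1.0)
    return agg


def consensus_partition(adjacency: np.ndarray, gamma: float = 1.0,
                        n_init: int = 1000, tau: float = 0.95, seed: int = 0,
                        max_iter: int = 50,
                        weight_matrix: np.ndarray | None = None) -> CommunitySolution:
    """Consensus over ``n_init`` seeded Louvain runs.

    Co-assignment frequencies form the agreement matrix; entries at or below
    ``tau`` are zeroed (strictly "more than tau" survives) and Louvain is
    re-run on the thresholded agreement until all runs coincide. Silhouettes
    (and the mean-silhouette confidence score) are computed on
    ``weight_matrix`` when given and the final partition has >= 2
    communities.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    W = _clean_adjacency(adjacency)

    partitions = [louvain_once(W, gamma, seed=seed + k)[0] for k in range(n_init)]
    agreement = _agreement(partitions)

    current = agreement
    for it in range(max_iter):
        thresholded = np.where(current > tau, current, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        runs = [louvain_once(thresholded, 1.0, seed=seed + 7919 * (it + 1) + k)[0]
                for k in range(n_init)]
        first = runs[0]
        if all(np.array_equal(first, r) for r in runs[1:]):
            final = first
            break
        current = _agreement(runs)
    else:
        raise ConsensusError(
            f"consensus did not stabilize in {max_iter} iterations "
            f"(gamma={gamma}, tau={tau}, n_init={n_init})")

    q = modularity_value(W, final, gamma)
    solution = CommunitySolution(gamma=float(gamma), partition=final,
                                 q_value=q, agreement=agreement)
    if weight_matrix is not None and np.unique(final).size >= 2:
        s = silhouette_scores(weight_matrix, final)
        solution.silhouettes = s
        solution.confidence = float(s.mean())
    return solution


def silhouette_scores(weighted_adjacency: np.ndarray,
                      partition: np.ndarray) -> np.ndarray:
    """Per-node silhouette S_i = (b_i - a_i) / max(a_i, b_i).

    Distance between nodes is d = 1 - w on the symmetrized weighted matrix
    (weights normalized to [-1, 1], so w = 1 means distance 0). ``a_i`` is
    the mean distance to the node's own community (self excluded; singleton
    communities score 0) and ``b_i`` the minimum over other communities of
    the mean distance to that community.
    """
    W = np.asarray(weighted_adjacency, dtype=float)
    W = (W + W.T) / 2.0
    partition = np.asarray(partition)
    comms = np.unique(partition)
    if comms.size < 2:
        raise ValueError(
            "silhouette undefined for a single community; supply a partition "
            "with >= 2 communities")
    d = 1.0 - W
    n = W.shape[0]
    scores = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero((partition == partition[i]) & (np.arange(n) != i))
        if own.size == 0:
            scores[i] = 0.0
            continue
        a = d[i, own].mean()
        b = min(d[i, partition == c].mean() for c in comms if c != partition[i])
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return scores


def gamma_sweep(binary: np.ndarray, weighted: np.ndarray,
                gammas: np.ndarray | None = None, n_init: int = 1000,
                tau: float = 0.95, seed: int = 0) -> GammaSweepResult:
    """Consensus clustering across resolutions for both matrix types.

    Silhouette confidence is always evaluated on the weighted matrix. The
    best solution maximizes confidence; ties resolve to the smallest gamma,
    binary before weighted. Solutions whose consensus collapses to a single
    community get NaN confidence and cannot be selected.
    """
    if gammas is None:
        gammas = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)
    rows = []
    solutions: dict[tuple[float, str], CommunitySolution] = {}
    for gamma in gammas:
        per_type: dict[str, CommunitySolution] = {}
        for mtype, matrix in (("binary", binary), ("weighted", weighted)):
            sol = consensus_partition(matrix, gamma=float(gamma), n_init=n_init,
                                      tau=tau, seed=seed, weight_matrix=weighted)
            sol.matrix_type = mtype
            per_type[mtype] = sol
            solutions[(float(gamma), mtype)] = sol
        identical = np.array_equal(
            _relabel(per_type["binary"].partition),
            _relabel(per_type["weighted"].partition))
        for mtype, sol in per_type.items():
            rows.append({
                "gamma": float(gamma), "matrix_type": mtype,
                "n_communities": sol.n_communities,
                "q_value": sol.q_value, "confidence": sol.confidence,
                "partitions_identical": identical,
            })
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["confidence"])
    if valid.empty:
        raise ConsensusError("no gamma produced a multi-community consensus")
    best_conf = valid["confidence"].max()
    tied = valid[valid["confidence"] >= best_conf - 1e-12]
    tied = tied.sort_values(["gamma", "matrix_type"])  # binary < weighted
    pick = tied.iloc[0]
    best = solutions[(float(pick["gamma"]), str(pick["matrix_type"]))]
    return GammaSweepResult(best=best, table=table, solutions=solutions)
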