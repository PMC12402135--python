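"""Cortico-subcortical convergence statistics.

Convergence is a many-to-one mapping: several cortical ROIs holding
*bidirectional* significant connectivity with one subcortical ROI (no
directionality implied). This module quantifies

* per-subcortical-ROI convergence counts (row sums of the bidirectional
  bipartite graph),
* proportion convergence O_ij between cortical pairs — the number of
  subcortical targets a pair shares, normalized so all pairs sum to 1,
* bilateral Euclidean distances between cortical ROIs (hemisphere-matched
  parcel distances, averaged),
* distance distributions of functionally-similar (same RSN) vs
  functionally-diverse (different RSN) pairs, binned at 8 mm and
  approximated with a normal curve,
* network-level primary:association convergence percentages per subcortical
  network, and the FS-vs-FD paired bin-wise t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_io import BinaryGraph, Parcellation, PRIMARY_NETWORKS

__all__ = [
    "ConvergenceDistributions",
    "bidirectional_graph",
    "convergence_counts",
    "proportion_convergence",
    "roi_distance",
    "pair_distance_matrix",
    "fs_fd_distributions",
    "fs_fd_paired_test",
    "network_level_convergence",
]


def bidirectional_graph(C: np.ndarray, cortical_idx: np.ndarray,
                        subcortical_idx: np.ndarray,
                        labels: list[str] | None = None) -> BinaryGraph:
    """Symmetric cortico-subcortical graph from a directed binary matrix.

    An edge (r, s) exists iff C[r, s] = 1 AND C[s, r] = 1 (strict
    bidirectionality — the "dual dyad" motif rationale), restricted to
    cortical-subcortical pairs; all other entries are dropped.
    """
    cortical_idx = np.asarray(cortical_idx, dtype=int)
    subcortical_idx = np.asarray(subcortical_idx, dtype=int)
    if np.intersect1d(cortical_idx, subcortical_idx).size:
        raise ValueError("cortical and subcortical index sets overlap")
    C = (np.asarray(C) != 0).astype(np.int8)
    both = C & C.T
    A = np.zeros_like(both)
    block = both[np.ix_(cortical_idx, subcortical_idx)]
    A[np.ix_(cortical_idx, subcortical_idx)] = block
    A[np.ix_(subcortical_idx, cortical_idx)] = block.T
    return BinaryGraph(adjacency=A, directed=False, labels=labels,
                       subsets={"cortical": cortical_idx,
                                "subcortical": subcortical_idx})


def _subsets(graph: BinaryGraph) -> tuple[np.ndarray, np.ndarray]:
    if not graph.subsets or not {"cortical", "subcortical"} <= graph.subsets.keys():
        raise ValueError("graph must carry 'cortical' and 'subcortical' subsets")
    return (np.asarray(graph.subsets["cortical"], dtype=int),
            np.asarray(graph.subsets["subcortical"], dtype=int))


def convergence_counts(graph: BinaryGraph) -> pd.Series:
    """Per-subcortical-ROI number of converging cortical connections."""
    cort, sub = _subsets(graph)
    counts = graph.adjacency[np.ix_(sub, cort)].sum(axis=1)
    index = ([graph.labels[i] for i in sub] if graph.labels
             else pd.RangeIndex(len(sub)))
    return pd.Series(counts, index=index, name="n_converging")


def proportion_convergence(graph: BinaryGraph) -> np.ndarray:
    """Proportion convergence O over cortical pairs.

    The raw count for pair (i, j) is the number of subcortical targets both
    connect to (only joint presence counts — joint absence carries no
    convergence); counts are normalized by their grand total so the upper
    triangle sums to 1. Returns the symmetric cortical x cortical matrix.
    """
    cort, sub = _subsets(graph)
    B = graph.adjacency[np.ix_(cort, sub)].astype(float)
    shared = B @ B.T
    np.fill_diagonal(shared, 0.0)
    if shared.sum() == 0:
        warnings.warn("no cortical pair shares a subcortical target",
                      RuntimeWarning, stacklevel=2)
        return shared
    # shared.sum() double-counts the unordered pairs; normalize so the upper
    # triangle sums to 1
    return shared / (shared.sum() / 2.0)


def roi_distance(parcellation: Parcellation, i: int, j: int) -> float:
    """Bilateral Euclidean distance between two ROIs in mm.

    For two bilateral ROIs, parcel distances are computed within each
    hemisphere (first-with-first, second-with-second as stored) and
    averaged. If either ROI is medial (single centroid), every centroid
    combination is averaged instead.
    """
    ci, cj = parcellation.centroids[i], parcellation.centroids[j]
    if not (np.isfinite(ci).all() and np.isfinite(cj).all()):
        raise ValueError(
            f"missing centroid for ROI {parcellation.labels[i]!r} or "
            f"{parcellation.labels[j]!r}")
    if ci.shape[0] == cj.shape[0] == 2:
        pairs = [(ci[0], cj[0]), (ci[1], cj[1])]
    else:
        pairs = [(a, b) for a in ci for b in cj]
    return float(np.mean([np.linalg.norm(a - b) for a, b in pairs]))


def pair_distance_matrix(parcellation: Parcellation,
                         indices: np.ndarray) -> np.ndarray:
    indices = np.asarray(indices, dtype=int)
    n = indices.size
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            D[a, b] = D[b, a] = roi_distance(parcellation, indices[a], indices[b])
    return D


@dataclass
class ConvergenceDistributions:
    bin_edges: np.ndarray
    fs_binned: np.ndarray
    fd_binned: np.ndarray
    fits: dict[str, dict[str, float]]
    fs_mask: np.ndarray  # upper-triangle boolean over pairs, FS class
    pair_weights: np.ndarray
    pair_distances: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.fs_binned.size


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2))


def _fit_class(weights: np.ndarray, distances: np.ndarray,
               binned: np.ndarray, edges: np.ndarray, method: str,
               label: str) -> dict[str, float] | None:
    total = weights.sum()
    if total == 0:
        warnings.warn(f"{label}: no convergence weight; fit omitted",
                      RuntimeWarning, stacklevel=3)
        return None
    if method == "moments":
        mu = float((weights * distances).sum() / total)
        var = float((weights * (distances - mu) ** 2).sum() / total)
        return {"mu": mu, "sigma": float(np.sqrt(var)), "method": "moments"}
    if method == "lsq":
        x = edges[1:]  # nominal bin position: upper edge of each 8-mm bin
        p0 = [float(binned.max()), float(x[np.argmax(binned)]), float(edges[-1]) / 4]
        try:
            popt, _ = optimize.curve_fit(_gaussian, x, binned, p0=p0, maxfev=20000)
        except RuntimeError:
            warnings.warn(f"{label}: histogram fit did not converge",
                          RuntimeWarning, stacklevel=3)
            return None
        return {"mu": float(popt[1]), "sigma": float(abs(popt[2])),
                "amplitude": float(popt[0]), "method": "lsq"}
    raise ValueError("fit method must be 'lsq' or 'moments'")


def fs_fd_distributions(O: np.ndarray, distances: np.ndarray,
                        rsn_labels: list[str] | np.ndarray,
                        bin_width: float = 8.0,
                        span: float | None = None,
                        fit: str = "lsq") -> ConvergenceDistributions:
    """Distance distributions of FS vs FD converging cortical pairs.

    A pair is functionally similar (FS) when both nodes carry the same RSN
    label and functionally diverse (FD) otherwise. Pair weights are the
    proportion-convergence entries; per class, weights are summed inside
    ``bin_width``-mm bins anchored at 0. ``span`` sets the binned range
    (default: the largest observed pair distance; the last bin always
    includes the maximum). The normal approximation per class is a
    least-squares Gaussian fit to the binned histogram (``fit="lsq"``,
    evaluated at the bins' upper edges) or the weight-weighted
    moments of the raw pair distances (``fit="moments"``).
    """
    O = np.asarray(O, dtype=float)
    distances = np.asarray(distances, dtype=float)
    rsn = np.asarray(rsn_labels)
    if O.shape != distances.shape or O.shape[0] != rsn.size:
        raise ValueError("O, distances and rsn_labels must align")
    n = O.shape[0]
    iu = np.triu_indices(n, k=1)
    w = O[iu]
    d = distances[iu]
    fs_mask = rsn[iu[0]] == rsn[iu[1]]

    observed_max = d[w > 0].max() if (w > 0).any() else d.max()
    if span is None:
        span = float(observed_max)
    if span < observed_max - 1e-9:
        raise ValueError("span smaller than the largest weighted pair distance")
    n_bins = max(1, int(np.ceil(span / bin_width - 1e-9)))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width

    def binsum(mask):
        idx = np.minimum((d[mask] // bin_width).astype(int), n_bins - 1)
        out = np.zeros(n_bins)
        np.add.at(out, idx, w[mask])
        return out

    fs_binned = binsum(fs_mask)
    fd_binned = binsum(~fs_mask)
    fits = {}
    for label, mask, binned in (("FS", fs_mask, fs_binned),
                                ("FD", ~fs_mask, fd_binned)):
        res = _fit_class(w[mask], d[mask], binned, edges, fit, label)
        if res is not None:
            fits[label] = res
    return ConvergenceDistributions(
        bin_edges=edges, fs_binned=fs_binned, fd_binned=fd_binned, fits=fits,
        fs_mask=fs_mask, pair_weights=w, pair_distances=d)


def fs_fd_paired_test(fs_binned: np.ndarray,
                      fd_binned: np.ndarray) -> tuple[float, int, float]:
    """Paired t-test of FD minus FS per-bin convergence weights.

    Returns (t, dof, p) with dof = n_bins - 1. A constant nonzero
    difference across bins yields an infinite-t sentinel (p = 0); identical
    vectors yield t = 0 (p = 1).
    """
    fs = np.asarray(fs_binned, dtype=float)
    fd = np.asarray(fd_binned, dtype=float)
    if fs.shape != fd.shape:
        raise ValueError("binned vectors must align")
    if fs.size < 2:
        raise ValueError("need at least 2 bins")
    diff = fd - fs
    dof = fs.size - 1
    # constant difference (up to float jitter): degenerate paired test
    if diff.std(ddof=1) < 1e-12 * max(1.0, float(np.abs(diff).max())):
        if diff.mean() == 0:
            return 0.0, dof, 1.0
        return float(np.sign(diff.mean()) * np.inf), dof, 0.0
    t, p = stats.ttest_rel(fd, fs)
    return float(t), dof, float(p)


def network_level_convergence(graph: BinaryGraph, parcellation: Parcellation,
                              subcortical_networks: list[str] | np.ndarray | None = None,
                              ) -> pd.DataFrame:
    """Primary vs association convergence percentages per subcortical
    network.

    Counts bidirectional connections from primary-class (VIS/SOM/CER) vs
    association-class cortical ROIs into each subcortical network. A network
    with no connections is reported with NaN percentages.
    """
    cort, sub = _subsets(graph)
    if subcortical_networks is None:
        subcortical_networks = [parcellation.rsn[i] for i in sub]
    subcortical_networks = np.asarray(subcortical_networks)
    if subcortical_networks.size != sub.size:
        raise ValueError("one network label per subcortical node required")
    is_primary = np.array(
        [parcellation.rsn[i] in PRIMARY_NETWORKS for i in cort])
    B = graph.adjacency[np.ix_(sub, cort)]
    rows = []
    for net in pd.unique(subcortical_networks):
        edges = B[subcortical_networks == net]
        primary = int(edges[:, is_primary].sum())
        association = int(edges[:, ~is_primary].sum())
        total = primary + association
        rows.append({
            "network": net,
            "primary_count": primary,
            "association_count": association,
            "primary_pct": 100.0 * primary / total if total else np.nan,
            "association_pct": 100.0 * association / total if total else np.nan,
        })
    return pd.DataFrame(rows).set_index("network")
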