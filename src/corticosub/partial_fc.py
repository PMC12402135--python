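"""Partial-correlation functional connectivity.

Subject-level connectivity is the matrix of node-wise multiple-regression
coefficients: each ROI's time course is regressed (no intercept; columns are
mean-centred) on the remaining N-1 ROIs, so ``beta[j, i]`` measures the
unique linear influence of ROI j on ROI i with all other ROIs partialled
out. Group-level edges come from entrywise one-sample t-tests across
subjects (random-effects analysis), Bonferroni-corrected by the number of
regressors. A phase-randomization surrogate test checks that observed
dependence exceeds what autocorrelation alone produces.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg, stats

from .core_io import ConnectivityResult, TimeSeriesPanel

__all__ = [
    "CollinearityError",
    "prepare_subject",
    "fit_partial_betas",
    "group_rfx",
    "phase_randomize",
    "surrogate_null_test",
]


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; offending columns are reported."""


def prepare_subject(panel: TimeSeriesPanel, subject: str,
                    n_discard: int = 100) -> np.ndarray:
    """Discard initial volumes, mean-centre per session, concatenate.

    Each of the subject's sessions loses its first ``n_discard`` rows (scanner
    steady-state transient), is column-mean-centred to remove the session's
    mean intensity, and the sessions are stacked row-wise.
    """
    blocks = []
    for key in panel.sessions_of(subject):
        mat = panel.data[key]
        if mat.shape[0] < n_discard + 2:
            raise ValueError(
                f"session {key} has {mat.shape[0]} volumes; needs more than "
                f"n_discard + 1 = {n_discard + 1}")
        block = mat[n_discard:]
        blocks.append(block - block.mean(axis=0, keepdims=True))
    return np.vstack(blocks)


def _collinear_columns(X: np.ndarray, rcond: float) -> list[int]:
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    bad = d < rcond * d.max()
    return sorted(int(piv[k]) for k in np.flatnonzero(bad))


def fit_partial_betas(X: np.ndarray, rcond: float | None = None) -> np.ndarray:
    """Node-wise OLS betas; entry (j, i) is the coefficient of column j in
    the no-intercept regression of column i on all other columns.

    Solved through the Gram matrix: with G = X'X and its inverse Theta, the
    coefficient of regressor j for target i is -Theta[j, i] / Theta[i, i]
    (the standard precision-matrix identity for saturated node-wise
    regressions), which matches the explicit normal-equations solution to
    machine precision while costing one factorization for all N targets.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D time x ROI matrix")
    n_t, n = X.shape
    if n_t <= n:
        raise ValueError(f"need more rows than columns (got {n_t} x {n})")
    if rcond is None:
        rcond = n_t * np.finfo(float).eps
    G = X.T @ X
    try:
        cf = linalg.cho_factor(G)
        theta = linalg.cho_solve(cf, np.eye(n))
    except np.linalg.LinAlgError:
        theta = None
    if theta is None or np.linalg.cond(G) > 1.0 / max(rcond, 1e-300) ** 2:
        bad = _collinear_columns(X, np.sqrt(rcond))
        raise CollinearityError(
            f"rank-deficient design; collinear columns: {bad}")
    betas = -theta / np.diag(theta)[None, :]
    np.fill_diagonal(betas, 0.0)
    return betas


def group_rfx(betas_by_subject: dict[str, np.ndarray] | list[np.ndarray],
              alpha: float = 0.05,
              n_comparisons: int | None = None,
              roi_labels: list[str] | None = None) -> ConnectivityResult:
    """Random-effects group inference on subject beta matrices.

    Entrywise one-sample t across subjects; an edge is kept when its
    two-sided p-value beats ``alpha / n_comparisons`` (default divisor:
    N - 1 regressors). The weighted matrix holds the mean beta of each
    significant edge, rescaled so the largest magnitude is 1. Edges with
    identical nonzero betas in every subject (zero variance) are treated as
    significant with an infinite-t sentinel; identically-zero edges are not.
    """
    if isinstance(betas_by_subject, dict):
        subjects = list(betas_by_subject)
        stack = np.stack([betas_by_subject[s] for s in subjects])
        betas_map = dict(betas_by_subject)
    else:
        stack = np.stack(list(betas_by_subject))
        subjects = [f"sub{i:02d}" for i in range(stack.shape[0])]
        betas_map = dict(zip(subjects, stack))
    n_sub, n, _ = stack.shape
    if n_sub < 2:
        raise ValueError("group inference needs at least 2 subjects")
    if n_comparisons is None:
        n_comparisons = n - 1
    dof = n_sub - 1

    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n_sub))
    zero_var = sd == 0
    t[zero_var & (mean != 0)] = np.inf * np.sign(mean[zero_var & (mean != 0)])
    t[zero_var & (mean == 0)] = 0.0
    np.fill_diagonal(t, 0.0)

    p = 2.0 * stats.t.sf(np.abs(t), dof)
    offdiag = ~np.eye(n, dtype=bool)
    binary = (p < alpha / n_comparisons) & offdiag
    weighted = np.where(binary, mean, 0.0)
    peak = np.abs(weighted).max()
    if peak > 0:
        weighted = weighted / peak
    return ConnectivityResult(
        roi_labels=roi_labels or [f"R{i:03d}" for i in range(n)],
        betas=betas_map, t_matrix=t, dof=dof,
        binary=binary.astype(np.int8), weighted=weighted,
        alpha=alpha, n_comparisons=n_comparisons)


def subject_betas(panel: TimeSeriesPanel, n_discard: int = 100) -> dict[str, np.ndarray]:
    """Per-subject partial betas after session preparation."""
    return {s: fit_partial_betas(prepare_subject(panel, s, n_discard))
            for s in panel.subjects}


def phase_randomize(series: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-randomized surrogate with the exact original amplitude spectrum.

    Columns of a 2-D input are randomized independently, which preserves each
    series' autocorrelation (power spectrum) but destroys genuine
    cross-series dependence. DC and (for even lengths) Nyquist bins keep
    their real amplitudes so the output is real with unchanged mean and
    variance.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n_t = x.shape[0]
    if n_t < 4:
        raise ValueError("series too short to phase-randomize")
    spec = np.fft.rfft(x, axis=0)
    n_f = spec.shape[0]
    hi = n_f - 1 if n_t % 2 == 0 else n_f  # exclude Nyquist bin when present
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(hi - 1, x.shape[1]))
    spec[1:hi] = np.abs(spec[1:hi]) * np.exp(1j * phases)
    out = np.fft.irfft(spec, n=n_t, axis=0)
    return out[:, 0] if squeeze else out


def surrogate_null_test(panel: TimeSeriesPanel, n_surrogates: int = 100,
                        n_discard: int = 100, seed: int = 0) -> dict:
    """Observed vs surrogate partial-correlation magnitudes.

    For every surrogate draw, each prepared subject matrix is column-wise
    phase-randomized and refit; the pooled two-sample t-test then compares
    the observed |beta| sample against the pooled surrogate sample. The two
    orderings of a pair estimate the same dependence and are nearly
    duplicate values, so each unordered pair contributes one magnitude (the
    mean of |beta_ij| and |beta_ji|) — keeping both would double-count and
    inflate the test. A significantly larger observed mean indicates
    genuine cross-series dependence beyond autocorrelation.
    """
    if n_surrogates < 2:
        raise ValueError("need at least 2 surrogates")
    prepared = {s: prepare_subject(panel, s, n_discard) for s in panel.subjects}
    n = len(panel.roi_labels)
    iu = np.triu_indices(n, k=1)

    def pair_magnitudes(B: np.ndarray) -> np.ndarray:
        A = np.abs(B)
        return (A[iu] + A.T[iu]) / 2.0

    observed = np.concatenate([
        pair_magnitudes(fit_partial_betas(X)) for X in prepared.values()])
    surrogate = []
    for k in range(n_surrogates):
        for si, X in enumerate(prepared.values()):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(k, si)))
            surrogate.append(pair_magnitudes(fit_partial_betas(phase_randomize(X, rng))))
    surrogate = np.concatenate(surrogate)

    t, p = stats.ttest_ind(observed, surrogate, equal_var=True)
    return {
        "t": float(t),
        "dof": int(observed.size + surrogate.size - 2),
        "p": float(p),
        "observed_mean": float(observed.mean()),
        "surrogate_mean": float(surrogate.mean()),
        "n_observed": int(observed.size),
        "n_surrogate_values": int(surrogate.size),
        "n_surrogates": int(n_surrogates),
        "seed": int(seed),
    }
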