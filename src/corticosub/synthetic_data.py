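"""Synthetic multi-subject resting-state panels with planted structure.

The generator emulates the statistical features the analysis pipeline relies
on, without any hemodynamic forward modelling:

* modular instantaneous dependence — innovations drawn from a block
  covariance with correlation ``rho_within`` inside planted communities and
  ``rho_between`` across them;
* temporal autocorrelation — an AR(1) recursion with coefficient ``phi``,
  scaled so the stationary marginal covariance equals the block matrix
  (``x_t = phi x_{t-1} + sqrt(1 - phi^2) e_t``);
* cortico-subcortical convergence — planted as direct conditional
  dependence: the innovation precision matrix receives an off-diagonal
  entry for every (subcortical target, cortical source) pair, sized so the
  pair's partial correlation equals the requested coupling strength. This
  keeps the conditional-dependence footprint exactly on the planted pairs
  (an additive shared-latent construction would instead leak negative
  partial correlations onto every conditioning partner of the sources);
* session effects — a constant per-(session, ROI) offset that the pipeline's
  mean-centering must remove.

Determinism: every (subject, session) stream is an independent
``SeedSequence(seed, spawn_key=...)`` substream of the panel seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Parcellation, TimeSeriesPanel

__all__ = [
    "SimulationSpec",
    "simulate_panel",
    "ground_truth",
    "block_covariance",
    "innovation_covariance",
    "default_parcellation",
    "make_recovery_spec",
]


@dataclass
class SimulationSpec:
    """Study-condition description for one synthetic panel.

    ``community_assignment`` is an integer label per ROI (the planted
    partition). ``convergence_plan`` is a list of
    ``(subcortical_roi, (cortical_roi, ...), coupling_strength)`` triples;
    the coupling strength is the planted partial correlation between the
    target and each source. ``subcortical_rois`` marks which ROIs play the
    subcortical role in downstream convergence analyses.
    """

    community_assignment: np.ndarray
    n_subjects: int = 20
    n_sessions: int = 2
    n_timepoints: int = 1100
    tr_seconds: float = 0.72
    rho_within: float = 0.6
    rho_between: float = 0.1
    ar_coefficient: float = 0.3
    convergence_plan: list[tuple[int, tuple[int, ...], float]] = field(default_factory=list)
    subcortical_rois: tuple[int, ...] = ()
    noise_sd: float = 0.0
    session_offset_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.community_assignment = np.asarray(self.community_assignment, dtype=int)
        if self.community_assignment.ndim != 1:
            raise ValueError("community_assignment must be a 1-D label vector")
        if not 0 <= self.rho_between < self.rho_within:
            raise ValueError("need 0 <= rho_between < rho_within")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if min(self.n_subjects, self.n_sessions, self.n_timepoints) < 1:
            raise ValueError("panel dimensions must be positive")
        for s, corticals, strength in self.convergence_plan:
            if s in corticals:
                raise ValueError("a ROI cannot converge onto itself")
        # positive definiteness of the innovation covariance (including
        # planted convergence entries), checked once
        np.linalg.cholesky(innovation_covariance(self))

    @property
    def n_rois(self) -> int:
        return self.community_assignment.size

    @property
    def roi_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_rois)]


def block_covariance(spec: SimulationSpec) -> np.ndarray:
    """Innovation covariance implied by the planted communities alone."""
    comm = spec.community_assignment
    same = comm[:, None] == comm[None, :]
    sigma = np.where(same, spec.rho_within, spec.rho_between)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def innovation_covariance(spec: SimulationSpec) -> np.ndarray:
    """Innovation covariance with planted convergence.

    The block covariance is inverted, each planted (target, source) pair
    receives a precision entry ``-strength * sqrt(theta_ss * theta_rr)``
    (so its partial correlation is the requested strength), and the matrix
    is inverted back and rescaled to unit variances.
    """
    sigma = block_covariance(spec)
    if not spec.convergence_plan:
        return sigma
    theta = np.linalg.inv(sigma)
    for target, corticals, strength in spec.convergence_plan:
        for roi in corticals:
            val = -strength * np.sqrt(theta[target, target] * theta[roi, roi])
            theta[target, roi] = theta[roi, target] = val
    try:
        np.linalg.cholesky(theta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "planted convergence makes the joint precision matrix "
            "non-positive-definite; lower the coupling strengths") from exc
    sigma = np.linalg.inv(theta)
    scale = np.sqrt(np.diag(sigma))
    return sigma / np.outer(scale, scale)


def _ar1(rng: np.random.Generator, chol: np.ndarray, n_t: int, phi: float) -> np.ndarray:
    """Stationary AR(1) with innovation covariance ``chol @ chol.T``."""
    n = chol.shape[0]
    innov = rng.standard_normal((n_t, n)) @ chol.T
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi ** 2)
    for t in range(1, n_t):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x


def simulate_panel(spec: SimulationSpec) -> TimeSeriesPanel:
    """Draw one panel; deterministic given ``spec.seed``."""
    sigma = innovation_covariance(spec)
    chol = np.linalg.cholesky(sigma)
    phi = spec.ar_coefficient
    data: dict[tuple[str, str], np.ndarray] = {}
    for si in range(spec.n_subjects):
        for se in range(spec.n_sessions):
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(si, se)))
            x = _ar1(rng, chol, spec.n_timepoints, phi)
            if spec.noise_sd > 0:
                x += rng.normal(0.0, spec.noise_sd, size=x.shape)
            x += rng.normal(0.0, spec.session_offset_sd, size=spec.n_rois)
            data[(f"sub{si:02d}", f"ses{se}")] = x
    return TimeSeriesPanel(roi_labels=spec.roi_labels, data=data,
                           tr_seconds=spec.tr_seconds)


def ground_truth(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Planted labels for recovery tests.

    Returns the planted partition and the symmetric 0/1 convergence
    adjacency holding every (subcortical target, cortical source) pair of
    ``convergence_plan``.
    """
    partition = spec.community_assignment.copy()
    adjacency = np.zeros((spec.n_rois, spec.n_rois), dtype=np.int8)
    for target, corticals, _ in spec.convergence_plan:
        for roi in corticals:
            adjacency[target, roi] = adjacency[roi, target] = 1
    return partition, adjacency


def default_parcellation(spec: SimulationSpec) -> Parcellation:
    """Synthetic ROI metadata matching the panel.

    Community ``c`` becomes network ``NET<c>``... except that downstream
    convergence analyses need the eight canonical cortical network names, so
    communities are mapped cyclically onto VIS, SOM, DAN, VAN, ... Centroids
    are seeded uniform draws inside a 140-mm box (bilateral, mirrored x);
    voxel counts are fixed at 100.
    """
    from .core_io import CORTICAL_RSNS

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(9999,)))
    comm = spec.community_assignment
    sub = set(spec.subcortical_rois)
    labels = spec.roi_labels
    rsn, roi_class = [], []
    for i in range(spec.n_rois):
        if i in sub:
            roi_class.append("subcortical")
            rsn.append(f"SUB{comm[i]}")
        else:
            roi_class.append("cortical")
            rsn.append(CORTICAL_RSNS[comm[i] % len(CORTICAL_RSNS)])
    centroids = []
    for i in range(spec.n_rois):
        right = rng.uniform((10, -70, -40), (70, 70, 70))
        left = right * np.array([-1, 1, 1]) + rng.normal(0, 2, 3)
        centroids.append(np.array([left, right]))
    return Parcellation(
        labels=labels, roi_class=roi_class, rsn=rsn, centroids=centroids,
        voxel_counts=np.full(spec.n_rois, 100, dtype=int),
    )


def make_recovery_spec(seed: int = 0, n_subjects: int = 20,
                       n_timepoints: int = 1100) -> SimulationSpec:
    """The reference parameter-recovery study conditions.

    30 ROIs in 3 planted communities of 10. Three nodes of every community
    play the subcortical role (so the subcortex itself spans three
    communities, as in the real organization), and six of the nine
    subcortical nodes each receive planted conditional dependence (partial
    correlation 0.05 — well above the detection threshold at these sample
    sizes, while keeping the joint precision matrix comfortably positive
    definite) with two cortical partners from other communities.
    """
    community = np.repeat([0, 1, 2], 10)
    subcortical = (7, 8, 9, 17, 18, 19, 27, 28, 29)
    plan = [
        (7, (10, 20), 0.05),
        (8, (11, 21), 0.05),
        (17, (0, 22), 0.05),
        (18, (1, 23), 0.05),
        (27, (2, 12), 0.05),
        (28, (3, 13), 0.05),
    ]
    return SimulationSpec(
        community_assignment=community,
        n_subjects=n_subjects,
        n_sessions=2,
        n_timepoints=n_timepoints,
        rho_within=0.6,
        rho_between=0.1,
        ar_coefficient=0.3,
        convergence_plan=plan,
        subcortical_rois=subcortical,
        seed=seed,
    )
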