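# Methods

This note records the scientific and numerical choices behind `corticosub`:
what each stage assumes, which knobs matter, and where the design was
genuinely open.

## Connectivity model

Subject-level connectivity is saturated node-wise regression: each
mean-centred ROI time course is regressed, without intercept, on all other
ROIs, so β_{j,i} is the partial (unique) linear influence of j on i. The
estimator is solved through the Gram matrix: with Θ = (XᵀX)⁻¹, the
coefficient of regressor j for target i is −Θ_{j,i}/Θ_{i,i}. This is
algebraically identical to solving each of the N normal-equation systems
and costs a single factorization; the test suite verifies agreement with
the explicit per-target solution at 1e−8. Rank deficiency is detected via
a Cholesky/condition check and reported with the offending columns (found
by pivoted QR). Assumptions: more time points than ROIs after discarding,
approximately stationary series, and linear dependence; no shrinkage or
autoregressive pre-whitening is applied (the surrogate test addresses
autocorrelation instead).

Group inference is a random-effects one-sample t-test per matrix entry
across subjects, Bonferroni-corrected by the number of regressors
(N − 1; configurable). Zero-variance entries are resolved by their limit
behaviour: identical nonzero betas are significant (infinite-t sentinel),
identically zero betas are not. The published method leaves open what the
group *weighted* matrix holds; here wC_{j,i} is the across-subject mean
beta where the group test is significant (else 0), rescaled so the largest
magnitude is 1. This is the single defensible reading of "significant
parameter estimates at group level" and is recorded in every report.

Two significance levels appear deliberately: α = 0.05 for the whole-brain
connectivity matrices and α = 0.01 for the convergence graph, both
Bonferroni-corrected, matching the analyses they feed.

## Surrogate test

Phase randomization keeps each series' amplitude spectrum (hence its
autocorrelation, mean and variance) and randomizes phases independently
per ROI, destroying genuine cross-series dependence. The test pools
observed vs surrogate partial-correlation magnitudes in a two-sample
pooled-variance t-test. One subtlety: |β_{ij}| and |β_{ji}| estimate the
same dependence and are nearly duplicate numbers; using both would halve
the effective sample and inflate the statistic (measured type-I ≈ 18% at a
nominal 5%). Each unordered pair therefore contributes one magnitude, the
mean of the two orderings (measured type-I ≈ 6%).

## Community detection

Louvain optimization runs on the symmetrized matrix (A + Aᵀ)/2 with
negative weights clipped to zero; modularity is always evaluated on that
same matrix by the package's own Q implementation, so every reported Q
equals a direct evaluation of the formula. Each seeded Louvain run is
followed by a greedy community-merge pass that accepts any pairwise merge
with positive ΔQ — this guarantees, for example, that γ = 0 collapses a
connected graph into one community, which stock Louvain implementations do
not always do.

Consensus: n_init seeded runs (seeds `seed + k`) build a co-assignment
agreement matrix; entries ≤ τ are zeroed (strictly "more than τ"
survives); Louvain at resolution 1 re-clusters the thresholded agreement
until all runs coincide (max 50 iterations, error with diagnostics
otherwise). An all-zero thresholded agreement yields singletons, which is a
stable, honestly-reported outcome.

Silhouettes use distance d = 1 − w on the symmetrized weighted matrix —
the simplest monotone map from connectivity strength to distance; w = 1
(the normalization peak) means distance 0. a_i excludes the node itself;
singleton communities score 0; b_i minimizes over all other communities in
the supplied partition. The γ-sweep always scores silhouettes on the
weighted matrix regardless of which matrix was clustered, so confidences
are comparable across matrix types. Ties in confidence resolve to the
smallest γ, binary before weighted; a consensus that collapses to one
community gets NaN confidence and cannot be selected.

## Graph metrics and nulls

All metrics run on an undirected unit-edge graph. The directed group
matrix is symmetrized with the OR rule by default (edge if either
direction is significant); the AND rule is available behind the same flag
and is *mandatory* for the convergence graph, where strict bidirectionality
is the defining criterion. Degenerate conventions: σ_m = 0 ⇒ z_i = 0;
k_i = 0 ⇒ P_i = 0; characteristic path length on a disconnected graph is
an error unless the caller opts into the largest component (reports say
when that happened). Null networks are degree-preserving double-edge swaps
(10 swaps per edge); every member's degree sequence is asserted equal to
the original, and a too-constrained graph produces a warning with the swap
budget recorded rather than a silent partial result. Null comparisons are
one-sample t-tests of the null distribution against the real value with
|t| and an explicit direction field, since the sign convention of such
tests is otherwise ambiguous.

## Convergence statistics

The proportion-convergence numerator counts subcortical targets shared by
a cortical pair, i.e. only joint presence. Read literally, a Kronecker
delta over connection indicators would also count joint *absence* as
convergence, which is clearly unintended; the package counts
c_{i,s} = c_{j,s} = 1.

ROI distances: bilateral ROIs contribute hemisphere-matched parcel
distances (left–left, right–right), averaged; a medial ROI (single
centroid, e.g. cerebellar vermis) pairs with each of the other ROI's
centroids and averages. Coordinates are used exactly as stored (MNI mm, no
axis flips).

Distance distributions: pair weights are summed in 8-mm bins anchored at
0 mm; the last bin absorbs the maximum. The binned range defaults to the
largest observed weighted pair distance. For comparison with the published
analysis the span is set to 168 mm (21 bins): the published histogram
covered the whole-brain cortical pair-distance range, which is wider than
the range spanned by the converging nodes alone (141 mm → 18 natural
bins; the extra bins are empty in both classes and enter the paired test
as zero differences).

The normal "approximation" of each class is, by default, a least-squares
Gaussian fit to the binned histogram, evaluated with each bin represented
by its upper edge. This choice is empirical: on the packaged table it
yields μ_FS = 33.58 mm, σ_FS = 24.67 mm, μ_FD = 60.08 mm, σ_FD = 28.18 mm,
against published values 33.18/22.58 and 60.10/28.19 — the FD parameters
match to printed precision, the FS mean to ~1%, while the alternative
O-weighted moment estimator (available via `fit="moments"`) is far off
(μ_FS = 44.25 mm). The residual FS discrepancy (+0.40 mm in μ, +2.09 mm in
σ) presumably reflects an undocumented detail of the original fit and is
reported as-is. The paired FD-vs-FS test is a textbook paired t on per-bin
summed weights (dof = bins − 1), with an infinite-t sentinel for a
constant nonzero difference and t = 0 for identical vectors.

The packaged table fixture keys cortical node identity on the printed
centroid pair: duplicate names with distinct centroids (three distinct
"Area 4 (M1)" parcels) are distinct nodes, while one parcel printed under
two names at identical centroids is a single node. Its integrity is
guarded by a checksum and by revalidating every per-ROI count against the
printed count column at load time.

## Attack simulation

Local efficiency follows the Latora–Marchiori convention: shortest paths
are confined to the subgraph induced by the removed node's neighbours
(`paths="full"` re-routes through the rest of the attacked graph instead;
it can only raise the value). Unreachable pairs contribute 0; fewer than
two neighbours give E = 0. The attack substrate is the converging
organization: all subcortical nodes plus every cortical node with at least
one bidirectional subcortical edge, with *all* OR-symmetrized significant
edges among them — cortico-cortical and subcortico-subcortical context
edges included, since a purely bipartite graph has edgeless neighbourhoods
and locally zero efficiency by construction. Random-attack nulls draw node
sets without replacement; because the LE of a set is the mean of per-node
neighbourhood efficiencies, those are computed once per pool and 10,000
draws cost almost nothing.

## Synthetic data

The generator produces what the pipeline consumes and nothing more:
jointly Gaussian AR(1) series (x_t = φx_{t−1} + √(1−φ²)e_t, stationary
covariance = innovation covariance), block-structured innovations
(correlation ρ_within inside planted communities, ρ_between across), a
constant per-(session, ROI) offset that the mean-centering step must
remove, and optional white measurement noise (default 0 — the innovations
are already stochastic). Planted convergence is written directly into the
innovation *precision* matrix: each (target, source) pair receives an
off-diagonal entry sized so its partial correlation equals the requested
coupling. An additive shared-latent construction was tried first and
rejected: conditioning on a latent's sources induces strong negative
partial correlations between the target and every other conditioning
partner of those sources, flooding the convergence graph with true-but-
unintended edges. The precision-domain construction confines conditional
dependence exactly to the planted pairs; positive definiteness is checked
at spec construction and fails loudly.

The reference recovery study (`make_recovery_spec`) uses 20 subjects,
2 sessions × 1100 time points, 30 ROIs in three communities of 10,
ρ_within = 0.6, ρ_between = 0.1, φ = 0.3. Three nodes per community play
the subcortical role (so the subcortex spans three communities, as in the
real organization) and six of them carry planted convergence with partial
correlation 0.05 — an order of magnitude above the detection threshold at
these sample sizes while keeping the joint precision matrix well
conditioned. When scoring convergence detection, within-community
cortico-subcortical pairs are excluded from both hits and false alarms:
they are conditionally dependent by construction (that is the planted
community structure), so only between-community pairs provide a true
null.

What the generator does *not* emulate: hemodynamics, scanner drift and
motion, non-Gaussian noise, spatial autocorrelation of parcels, and
between-subject heterogeneity (all subjects share one generative
distribution). Passing recovery tests therefore demonstrate correctness of
the estimators and pipeline wiring under the stated statistical model, not
robustness to fMRI artefacts.

## Problem sizes and determinism

Defaults in the orchestrating pipeline are sized for interactive use:
250 consensus initializations, 200 rewired nulls, 2000 attack draws; each
knob accepts the larger published-scale values (1000 inits, 1000 nulls,
10,000 draws) and the full reference recovery study runs in a few seconds
either way. Every stochastic component takes an explicit seed;
per-(subject, session) and per-surrogate streams derive from
`SeedSequence(seed, spawn_key=...)`, consensus initializations use
`seed + k`, and identical configuration plus seed reproduces every report
byte for byte.

## Known limitations

* The silhouette distance d = 1 − w and the group-weight definition are
  single defensible readings of loosely specified steps; both are
  configurable and recorded in reports.
* The surrogate test treats pair magnitudes as exchangeable across pairs;
  residual cross-pair dependence keeps its size slightly above nominal
  (≈6% measured at 5%).
* The published whole-sample statistics that require the original
  92-subject imaging panel (e.g. subcortical silhouette 0.38 ± 0.11,
  Q = 0.47, λ = 2.18, LE_target = 0.57) are outside what desk-scale
  synthetic data can reproduce; the package reproduces the table-derived
  convergence results exactly and validates the data-dependent stages by
  parameter recovery instead.
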