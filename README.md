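# corticosub

Analysis toolkit for the resting-state organization of the human subcortex
and its convergence with cortex. The package takes multi-subject,
multi-session ROI time series (delimited text), estimates group-level
partial-correlation functional connectivity, detects subcortical
resting-state communities with consensus Louvain clustering, validates them
against degree-preserving null networks, classifies hub types, quantifies
the many-to-one cortico-subcortical *converging organization*, and probes
its robustness with targeted node attacks. It is written for network
neuroscientists who want each of those stages as a tested, seedable library
function (or CLI subcommand) rather than a monolithic script.

## The model and statistics

**Partial-correlation connectivity.** For each subject, every ROI time
course X_i (sessions: first 100 volumes discarded, mean-centred,
concatenated) is regressed without intercept on the remaining N−1 ROIs;
β_{j,i} is the unique (partial) influence of ROI j on ROI i. Group edges
come from entrywise one-sample t-tests across subjects (random-effects),
two-sided p < α Bonferroni-corrected by the N−1 regressors, giving a
directed binary matrix C and a weighted matrix wC of mean significant betas
normalized to [−1, 1]. A phase-randomization surrogate test (amplitude
spectra preserved, phases randomized) checks that observed dependence
exceeds pure autocorrelation.

**Communities.** Louvain modularity optimization (resolution γ swept 0–2 in
0.1 steps, many seeded initializations) is aggregated through a
co-assignment agreement matrix thresholded at τ = 0.95 and re-clustered
until stable. Per-node silhouettes S_i = (b_i − a_i)/max(a_i, b_i), with
distance d = 1 − w on the weighted matrix, give the assignment-confidence
score that selects γ.

**Validation and hubs.** Within-module degree z-scores
z_i = (k_im − k̄_m)/σ_m, participation coefficients
P_i = 1 − Σ_m (k_im/k_i)², modularity Q and characteristic path length λ
are compared against 1000 degree-preserving rewired null networks
(one-sample t-tests). Nodes are typed by (P_i, z_i): connector hub
(P > 0.5, z > 0), non-hub connector, provincial hub, non-hub.

**Convergence.** A cortical ROI converges on a subcortical ROI when the
binary connectivity is *bidirectional* (C_{r,s} = C_{s,r} = 1). Per
subcortical ROI, N_s^conv = Σ_r c_{r,s}. The proportion convergence O_{i,j}
of a cortical pair counts the subcortical targets both connect to,
normalized so all pairs sum to 1. Pair distances are hemisphere-matched
bilateral Euclidean centroid distances (mm), averaged; pairs are
functionally similar (FS, same resting-state network) or functionally
diverse (FD), their O-weighted distance histograms (8-mm bins) are
approximated with normal curves, and per-bin FD−FS weights are compared
with a paired t-test.

**Attack robustness.** The local efficiency of a node's neighbourhood,
E(G_i) = (1/(N_i(N_i−1))) Σ_{j≠k} 1/l_{jk} after removing node i, is
averaged over an attacked node set; the targeted subcortical attack is
compared against 10,000 random attacks of the same size (whole-graph and
cortical-only pools).

A packaged fixture encodes the published convergence table: 27 subcortical
ROIs, the 71 distinct converging cortical ROIs with centroids and network
labels, and the bipartite convergence graph — so all convergence-level
statistics are reproducible without any imaging data. The synthetic-data
module generates seeded panels with planted communities (block-structured
AR(1) innovations) and planted cortico-subcortical conditional dependence,
used to test every data-dependent stage.

## Worked example

```python
from corticosub import (load_table1_fixture, convergence_counts,
                        network_level_convergence, proportion_convergence,
                        fs_fd_distributions, fs_fd_paired_test)
from corticosub.convergence_stats import pair_distance_matrix

parcellation, graph = load_table1_fixture()
counts = convergence_counts(graph)
print(f"max convergence: {counts.idxmax()} with {counts.max()} cortical partners")

print(network_level_convergence(graph, parcellation)[
    ["primary_pct", "association_pct"]].round(1))

O = proportion_convergence(graph)
cort = graph.subsets["cortical"]
D = pair_distance_matrix(parcellation, cort)
rsn = [parcellation.rsn[i] for i in cort]
dist = fs_fd_distributions(O, D, rsn, bin_width=8.0, span=168.0)
for cls, fit in dist.fits.items():
    print(f"{cls}: mu = {fit['mu']:.2f} mm, sigma = {fit['sigma']:.2f} mm")
t, dof, p = fs_fd_paired_test(dist.fs_binned, dist.fd_binned)
print(f"FD vs FS paired t[{dof}] = {t:.2f}, p = {p:.4f}")
```

prints

```
max convergence: AMY-m with 16 cortical partners
         primary_pct  association_pct
network
THA             80.0             20.0
BGN             40.0             60.0
SLN             19.2             80.8
FS: mu = 33.58 mm, sigma = 24.67 mm
FD: mu = 60.08 mm, sigma = 28.18 mm
FD vs FS paired t[20] = 3.52, p = 0.0022
```

Reading: the medial amygdala receives bidirectional connectivity from 16
distinct cortical regions — the strongest convergence in subcortex. The
thalamic network draws 80% of its converging connections from primary
networks (visual, somatomotor, cerebellum), the subcortical-limbic network
81% from association networks, with basal ganglia intermediate. Converging
FS pairs sit ~34 mm apart on average while FD pairs sit ~60 mm apart, and
FD pairs carry significantly more convergence weight per distance bin —
convergence is dominated by functionally diverse, spatially distant
cortical pairs.

The same stages run from the shell: `corticosub simulate | fc |
communities | validate | hubs | converge | attack | pipeline` (see
`corticosub --help`).

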