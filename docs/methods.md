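# Methods

This note records the models and procedures `occnet` implements, the
parameters that matter, the synthetic designs the tests rely on, and the
design decisions taken where the published descriptions left choices
open.

## SparCC estimation

**Model.** Observed abundances are treated as compositions of latent
absolute abundances whose logs have per-taxon variances ω and pairwise
correlations ρ. The log-ratio variance t_ij = Var[log(x_i/x_j)]
(computed with the n−1 sample variance) satisfies
t_ij = ω_i + ω_j − 2ρ_ij√(ω_iω_j). Summing over j and dropping the
correlation terms — justified only when the true network is sparse —
gives the linear system M ω = rowsum(t) with M = **1** + (D−2)I, after
which ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_iω_j)), clamped to [−1, 1].

**Exclusion iterations.** Pairs that come out strongly correlated
violate the sparsity assumption and bias ω. The estimator therefore
repeatedly finds the strongest off-diagonal |ρ| and, while it exceeds
the exclusion threshold (default 0.10) and fewer than the exclusion
maximum (default 10) pairs have been removed, drops that pair from both
M and the row sums and re-solves. Ties break on the lexicographically
lowest (row, col) pair so runs are deterministic. Excluded pairs still
receive a ρ from the final ω. A taxon whose solved ω is ≤ 0 is
degenerate — its t values are inconsistent with any positive basis
variance — and its correlations are reported as 0 with the diagonal kept
at 1; the flags are returned rather than silently clamped.

**Zero handling and aggregation.** Each of the 50 outer iterations draws
per-sample fractions from Dirichlet(counts + 1), which guarantees strict
positivity and propagates count uncertainty; the per-iteration estimates
are aggregated by the entrywise median, a robust choice matching the
reference behavior. Per-iteration RNG streams are spawned from the
single seed via `SeedSequence`, so results are reproducible and
independent of any parallel execution order.

**Disk-backed estimation.** With `scratch_path` set, each iteration's
ρ matrix is written to an HDF5 dataset (`/iter_<k>/rho`) and the median
is taken in blocks of 512 rows streamed across iterations, so the
memory high-water mark of the aggregation stage scales with
`block × n_taxa × n_iterations` rather than `n_taxa² × n_iterations`.
The in-memory and disk-backed paths produce bit-identical results (this
is tested).

**p-values.** Each permutation shuffles every taxon's counts across
samples independently, destroying between-taxon association while
preserving marginals, and re-runs the estimator. Permutation runs use 5
outer iterations instead of 50 — the permuted statistic's null location
is unaffected and this keeps 100 permutations affordable; the setting is
exposed (`permutation_iterations`). One-sided p-values use the upper
tail for ρ ≥ 0 and the lower tail for ρ < 0 with the add-one estimator
p = (1 + #exceed)/(n + 1), bounded in [1/(n+1), 1]; the two-sided option
uses |ρ|. Defaults: 100 permutations for pipeline runs, 50 in
quick mode (`SparccConfig.quick()`).

## Abundance filtering

A taxon is removed as a *singleton* when its total count across samples
is strictly below 5 (a total of exactly 5 survives) and as *unique* when
it has a nonzero count in exactly one sample. "Present" means count > 0.
When the input is already relative (every sample sums to 1) the
total-count rule is meaningless and only the unique rule is applied,
with a warning. Filtering is idempotent and never alters surviving
counts or sample order.

## UMAP + HDBSCAN visualization

Taxa are points; features are their per-sample relative abundances
(counts are closed per sample before embedding, since Bray–Curtis is
designed for compositions; a raw mode is available). Defaults: 15
neighbors, minimum distance 0.1, 2 components, Bray–Curtis input metric,
Hellinger output metric; HDBSCAN with Bray–Curtis on the embedding,
minimum cluster size 15, minimum samples 5; outliers flagged above the
0.9 quantile of GLOSH scores. Clustering runs on a precomputed
Bray–Curtis distance matrix of the embedding coordinates.

GLOSH scores are computed from the same density hierarchy HDBSCAN uses:
core distances at k = min_samples, mutual-reachability distances,
single-linkage tree, condensed with the minimum cluster size; a point
leaving its cluster at density λ_p scores
(λ_max − λ_p)/λ_max where λ_max is the densest level reached in that
cluster's subtree. Scores lie in [0, 1].

**Known limitation.** With the default Hellinger *output* metric the
embedded clusters are markedly more diffuse than with a Euclidean
output space: on the planted three-block benchmark below, HDBSCAN
recovers the blocks essentially perfectly under a Euclidean output
metric (adjusted Rand ≥ 0.9) but poorly under Hellinger. Both are
exposed; the recovery tests and examples therefore use
`output_metric="euclidean"`, the configuration the reference case
studies themselves used, while the package default follows the
published default. Seeded runs are deterministic on one machine (UMAP
is forced single-threaded when seeded).

## Network construction

Nodes are taxa; an included pair (i, j) becomes an undirected edge with
`raw_weight` = ρ_ij and `norm_weight` = (ρ_ij + 1)/2 ∈ [0, 1]. The
affine map is strictly increasing, so sign information survives as
norm > 0.5 ⇔ raw > 0. Edge inclusion is explicit: by p-value
(p < α, default α = 0.05), by magnitude (|ρ| ≥ threshold, default 0 —
the full matrix), or all pairs; the default picks the p-value rule when
p-values exist and the non-destructive magnitude rule otherwise, because
no destructive threshold is part of the published analyses. All
topological metrics downstream run on the unweighted edge set; raw signs
feed only the sign ratio and the balance census.

## Topology comparison

The summary reports node/edge counts, density, mean and SD of degree
(population SD, matching `numpy.std`), positive:negative edge ratio
(+inf when no negative edges), average shortest path and diameter (on
the giant component when disconnected, flagged), average clustering,
modularity of the greedy-modularity partition, and the small-world index
SW = (cc/cc_rand)/(l/l_rand) averaged over 50 matched Erdős–Rényi
graphs. SW of a random graph concentrates near 1; SW > 1 indicates
small-world structure. Edgeless networks yield NaN markers, not errors.

Null distributions are built from graphs matched on node count, density
and average degree: Erdős–Rényi G(n, p = density); Watts–Strogatz with
ring degree k = round(avg degree) forced even and rewiring probability
0.1; Barabási–Albert with attachment m = round(avg degree / 2). These
are the standard matchings given that only node count, density and
average degree are constrained. For every metric the observed value's
empirical quantile within each null is reported.

Degree distributions use unit-width integer bins by default (exact for
degrees); pdf = frequency/total, cdf is the cumulative sum, and
CCDF = 1 − CDF, which ends at 0 and is non-increasing. `compare_ccdf`
puts the observed curve next to one matched replicate per topology on
shared bins for log-log plotting.

## Structural balance

A triangle is balanced iff the product of its three edge signs is
positive: (+,+,+) and (+,−,−) balanced; (+,+,−) and (−,−,−) imbalanced.
The default census enumerates **every** triangle via ordered neighbor
intersection and is verified against brute-force triple enumeration. A
`cycle_basis` mode restricts the census to length-3 cycles of a cycle
basis; a cycle basis does not contain every triangle of a graph, so
this mode undercounts and exists only for comparison with pipelines
that used it. Exact zero weights are treated as non-edges.

## Percolation

Removal is cumulative without replacement until the network is empty:
ceil(step_fraction × original n) nodes per step (default 0.1), or one
whole group per step for the group strategy (size-descending order
unless given). Centrality strategies rank once on the intact network —
the published description removes "by centrality, higher values first"
with no recomputation language — and an adaptive re-ranking mode is
available behind a flag. After every step the simulation records
density, average degree, component count, giant-component size and
fraction, Louvain community count and modularity (per-step seeds derive
from the run seed). The robustness report integrates each metric over
the removed fraction (trapezoid) and reports the removal fraction at
which the giant fraction first drops below 0.5.

## Communities and centralities

Louvain runs on the binary edge set by default (a weighted flag uses
normalized weights); HDBSCAN labels can be imported as the partition,
with −1 mapped to a "noise" group and excluded from nothing except by
flag. Per group, the induced subgraph's node/edge counts, density,
average degree, clustering, and giant-component diameter and average
path are reported, plus phylum composition (second `;`-field of the
taxonomy, "NA" when unassigned). Groups of one node are flagged
noise-like. Centralities: degree, closeness (component-scaled
convention, well defined on disconnected graphs), normalized
betweenness (exact to 5,000 nodes, k = 1000 source samples above), and
PageRank with damping 0.85 on reciprocal links; rank columns break ties
by taxon id.

## Synthetic benchmarks

`generate_community` draws, per sample, latent log abundances from
N(log_mean, S ρ S) with S = diag(log_sd), closes the exponentials to
fractions, and draws multinomial counts at the configured depth. The
validation design regenerated by the tests and the acceptance script is
50 taxa × 200 samples at depth 10,000 with log_mean 0 and log_sd 1 —
the multinomial log-normal design standard for this estimator family;
the planted basis has 10 pairs at |ρ| = 0.8 on an identity background.
Planted pairs are sampled node-disjoint whenever they fit
(2·n_strong ≤ n_taxa), which keeps the matrix exactly PSD and the
planted values exact; otherwise arbitrary pairs are planted and the
matrix is projected to the nearest PSD correlation by eigenvalue
clipping and diagonal rescaling. `generate_signed_network` plants a
canonical topology and draws weight magnitudes uniform in (0, 1] with a
configurable negative-sign fraction (exact zeros would be non-edges).

**What the generator does not emulate.** Real amplicon data carry
overdispersion beyond multinomial sampling, taxon-specific detection
biases, and structured (not identity-background) correlation; passing
the planted-recovery tests shows the estimator and analyses are
implemented correctly under their own model assumptions, not that field
data meet those assumptions.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 50 × 200 validation design
with default estimator settings (5 seeds, a few seconds in total);
embedding tests use 90 taxa × 60 samples, and network analyses use
graphs of 100–200 nodes, sizes at which every property checked is
already stable. Tolerances: symmetry to 1e-12, the D = 3 closed-form
equivalence to 1e-10, probability simplex sums to 1e-9. Degenerate
inputs (edgeless graphs, triangle-free graphs, all-positive networks,
empty abundance tables) return documented markers (NaN, +inf) or typed
errors rather than crashing mid-pipeline.
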