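# Methods

This note documents the models, estimators, and numerical choices behind
`conet`, what the synthetic benchmarks do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Count-table processing

A count table holds non-negative reads of taxonomic features across
samples, optionally with seven-rank lineages (kingdom … species).
Filtering removes shallow samples first (total reads < `sample_sum_min`,
default 500), then features failing any of: prevalence (fraction of
retained samples with a nonzero count) below `prevalence_min`, **mean**
relative abundance below `abundance_min`, or total count below
`obs_sum_min`. Defaults are the stringent setting (0.05 / 0.01 / 100);
the relaxed setting (2/S / 0.001 / 10) is what the benchmark protocol
applies before inference. The abundance rule is read as mean rather than
per-sample maximum relative abundance — the stricter and more common
convention — and is configurable.

Taxonomic grouping sums rows sharing the identical lineage prefix at the
requested rank; a feature unresolved at that rank keeps its deepest
non-empty prefix as its key, so a family-level entity remains a distinct
node from genus-level entities of the same family. Column sums are
conserved exactly.

Transforms: total-sum scaling (columns sum to 1), centered log-ratio
(pseudocount default 1; columns sum to 0 within 1e-9), and rarefaction
(multivariate-hypergeometric subsampling without replacement, seeded;
disabled by default). CLR output is flagged so count-only operations
reject it.

## Inference methods

The consensus stage needs several estimators with different error
modes. The default roster is {`sparcc`, `rho`, `clr_sparse`} — two
compositionality-aware correlation estimators and one
conditional-independence estimator. Pearson and Spearman are implemented
for comparison but excluded from the default consensus, since they
produce abundant spurious edges on compositional data.

- **sparcc.** Fractions are estimated deterministically as
  (count+1)/(total+D) (a Dirichlet-posterior mean; full Dirichlet
  resampling is available behind `sparcc_resamples` with a seed). The
  variation matrix t_ij = Var(log f_i/f_j) comes from one covariance
  computation on log fractions; basis variances solve
  ((D−2)I + 11ᵀ)ω = Σ_j t_·j. Up to `sparcc_iterations` (default 20)
  exclusion rounds remove the most correlated pair above
  `sparcc_exclusion_threshold` (default 0.1) from the system, never
  reducing a feature below two remaining pairs. Estimated basis
  variances are floored at 1e-12 and correlations clipped to [−1, 1].
- **rho.** Proportionality ρ = 2·cov(z_i, z_j)/(var z_i + var z_j) on
  clr-transformed pseudocount fractions; equals 1 exactly for identical
  parts.
- **clr_sparse.** Graphical lasso on the correlation matrix of clr data
  at `sparse_penalty` (default 0.1); selected edges get signed partial
  correlations. The clr covariance is exactly singular (features sum to
  zero within each sample), so 1% identity shrinkage is applied before
  the solve; if the coordinate-descent solver stalls — it can cycle on
  near-collinear matrices — the fit escalates through larger shrinkage
  and the LARS solver before raising an error that suggests a larger
  penalty. No p-values are attached: the penalty is the selection, as is
  standard for regularized estimators.

Constant features produce zero correlations with a warning rather than
NaN. All correlation estimators require ≥ 4 samples.

## Permutation null and Brown merging

Each correlation method's p-values come from a permutation null in which
every feature's counts are shuffled independently across samples: this
destroys all cross-feature association while preserving marginals, and
the method's own transform is re-applied to each permuted table, so the
null also carries the compositional artifacts the method would see under
independence. The two-sided empirical p-value uses the add-one rule, so
the smallest attainable value is 1/(n_perm+1); the default 1000
permutations gives 1/1001.

The per-method matrices are merged with Brown's method. Fisher's
statistic ψ_j = −2 Σ_i log p_j^i is referred to c·χ²_{2f} with moments
matched to μ = 2k and σ² = 4k + 2 Σ_{i<i′} cov(−2 log p^i, −2 log p^i′):
c = σ²/2μ and f = μ²/σ². The inter-method covariance is estimated
empirically across the off-diagonal edges — with thousands of edges this
is simpler and at least as accurate as polynomial approximations. The
two limiting cases are exact: independent methods give c = 1, f = k
(Fisher), and perfectly duplicated methods give c = 2, f = 1, returning
the input p-values. k = 1 returns the input unchanged. p-values are
clipped to [1e-300, 1] before logs; non-positive inputs are an error.

Direct-association networks carry no p-values, and the p-value filter is
a no-op for them (weight filter only).

## Consensus

Inputs are thresholded networks aligned on the sorted union of node
sets; nodes missing from a network are padded as isolated (zero weights,
p = 1, so padding can never pass a significance filter). Simple voting
counts sign-consistent reports, M_j = max(#neg, #pos), and keeps an edge
iff M_j ≥ ⌊θw⌋; an explicit M_j ≥ 1 guard keeps universally absent edges
out at small θ, where the floor alone would be 0. The scaled sum
rescales each network by its maximum absolute weight (an all-zero
network contributes zero, with a warning), sums per edge, and keeps
|s_j| > (w−1)θ — strict inequality, as defined; the (w−1) scaling is
part of the rule's definition and kept as is. Consensus edges carry
every method's weight (a multigraph annotation), the Brown-merged
p-value when available, and a summary sign: sign(s_j) for SS, majority
sign for SV with ties broken by the largest-magnitude report.

Both rules are monotone in θ (nested edge sets), which is the mechanism
behind the precision/sensitivity trade-off the benchmarks measure.
Defaults: SS with θ = 0.333; the recommended SV operating point is
θ = 1.0.

## Synthetic benchmarks

The generators define the conditions under which the consensus is
evaluated. Both return the generating interaction support as ground
truth and are bit-reproducible under a seed.

**Klemm-Eguíluz graphs.** Clique-seeded growth with activation /
deactivation: each new node attaches to all active nodes (each
attachment rewired with probability μ to a degree-proportional non-active
node), then becomes active, deactivating one active node with
probability ∝ 1/degree. At μ = 0 the edge count is exactly
m(m−1)/2 + (N−m)m. Benchmark collections use N = 50, clique size 3
(≈ 12% connectance, in the sparse range typical of such benchmarks),
μ = 0.3.

**gLV endpoints.** dx_i/dt = x_i(b_i + Σ_j a_ij x_j); off-diagonal
interactions are drawn on the graph support with magnitude U(0, 0.2) and
random sign (independently per ordered pair, so A may be asymmetric;
evaluation uses the union support), self-limitation a_ii = −0.5, base
growth rates b_i ~ U(0, 1). Per sample, a Poisson(100)+1 initial
condition is integrated to t = 100 with LSODA (rtol 1e-6, atol 1e-8),
endpoint abundances below 1e-6 are treated as extinct, and counts are
drawn multinomially at 25 000 reads. Divergent trajectories are redrawn
up to 5 times.

One modeling choice matters greatly here: with a single growth-rate
vector shared by all samples, this weakly-interacting system has one
globally attracting equilibrium that is reached long before t = 100
(relaxation times are ~1/b_i), so endpoints would differ only by read
sampling noise and no estimator could recover anything. Samples
therefore receive a mean-preserving multiplicative log-normal jitter on
the growth rates (σ = 0.3, configurable), modeling environmental
variation across samples; each sample then relaxes to its own
equilibrium x* = −A⁻¹b_s, and the cross-sample abundance covariance is
shaped by the interaction matrix. The jitter scale was chosen so that a
zero-interaction community shows no association above 0.3 at moderate
sample sizes (the negative control) while interacting communities carry
recoverable signal.

**NorTA copulas.** A precision matrix is built on the topology support
with edge entries ±0.3 (random sign), diagonally loaded just enough to
be positive definite with condition number ≤ `condition_target`; its
inverse is scaled to a correlation matrix, MVN draws are mapped through
Φ and the target count quantile (Poisson μ = 50; negative binomial mean
50, dispersion 0.5, i.e. var = μ + 0.5μ²; ZINB additionally 30% zero
inflation; a user count table can be supplied to fit margins instead).
Margins are preserved exactly regardless of the correlation structure —
the margin-consistency check uses a discrete-aware KS statistic, since
the textbook KS p-value is anti-conservative on tied counts. The
condition target defaults to 5: this keeps partial correlations ≈ 0.3
and lets marginal correlation decay within a couple of graph hops.
Heavier loading (large condition numbers) makes the covariance nearly
singular and floods the whole graph with strong long-range correlations
that no longer resemble sparse ecological association structure. Six
topologies are available (band, cluster, scale-free, Erdős–Rényi, hub,
block), each at ≈ 2 edges per node.

**What the benchmarks do not emulate.** Sequencing error, chimeras,
taxonomy misassignment, uneven library sizes, time-series dependence,
and host/environment covariates are absent. Passing benchmarks shows the
estimators and consensus recover known dependence structure from
compositional counts under these idealized conditions — not that real
amplicon workflows achieve the same precision.

**Benchmark protocol.** Count tables pass through the relaxed filter
(prevalence 2/S, abundance 0.001, observation sum 10) before inference,
as the pipeline always filters before the inference step; this also
removes near-extinct gLV species whose clr rows are exactly collinear.
Inference runs the default roster, 1000 permutations, Brown merging,
weight 0.1 / p 0.05 thresholds, then the θ grid {0, 0.333, 0.5, 0.667,
1.0}. Collections of 12 NorTA (cycling band/cluster/scale-free, N = 50,
S = 500, NB margins) and 10 gLV datasets (N = 50, S = 100) keep the full
run within a few CPU-minutes; precision means are reported skipping
datasets with empty predictions (undefined precision is NaN, not 0, so
aggregation skips rather than penalizes).

With this three-method roster the scaled-sum consensus at θ = 1 is
essentially perfect (mean precision ≈ 0.97–1.0), and precision falls to
≈ 0.7 (NorTA) and ≈ 0.5 (gLV) at θ = 0.333. A larger roster dominated by
several independent sparse estimators raises the θ = 0.333 operating
point substantially: with w networks the SS cutoff is (w−1)θ, so at
w = 8 two correlated compositional-correlation methods can never carry
an edge by themselves, while at w = 3 they can — a known limitation of
small consensus rosters rather than of the consensus rule.

## Variance attribution

The W networks of an ensemble are flattened into a q² × W matrix; PCA
over networks (observations) retains the smallest number of components
whose cumulative explained variance reaches the target (default 0.95,
since there is no canonical c). Each component score vector is fit by an
additive linear model on all categorical workflow factors; ANOVA sums of
squares are Type II by default (robust to the imbalance that arises when
some tool combinations fail; Type I available), converted to fractions
of the component's total SS, and averaged across components with
explained-variance weights — the regression lives in component space, so
the aggregation does too. The residual is reported as 100 − Σ factor
shares; it absorbs interaction effects, which the additive model
deliberately omits. Aliased (perfectly confounded) factor pairs are
rejected by name; the model requires more networks than parameters.

## Reproducibility

Every stochastic routine takes a seed and regenerates bit-identically.
The pipeline fans one seed out to per-stage seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, so any stage can be
reproduced in isolation; consensus JSON output is byte-identical across
runs with the same config. JSON serialization stores each undirected
edge once (source < target) and round-trips weights and p-values at full
precision.

## Known limitations

- The default consensus roster has only one conditional-independence
  member; θ = 0.333 precision is correspondingly limited (see above).
- SparCC p-values come from the shared permutation null, not from
  bootstrap resampling; bootstrap confidence intervals are out of scope.
- Node identity is the exact lineage-prefix string; entities resolved to
  different ranks of the same lineage are distinct nodes, and no fuzzy
  lineage matching is attempted.
- The gLV generator returns endpoint snapshots only; time-series
  benchmarks and alternative noise models are out of scope.
- No FDR correction is applied: filtering uses the merged p-value at the
  stated cutoff directly.
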