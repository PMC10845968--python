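# Methods

## Scope and data model

The package analyses replicated compositional surveys: `G` groups
(developmental stages A/F/P/M, or organs R/St/L/S) × `r` replicates,
default 4 × 3 = 12 samples. All computations run on an `AbundanceTable`
(samples × taxa, non-negative integer counts), a rooted `PhyloTree`
with branch lengths, and a `CompoundTable` (mg/g for OMA, MA, SC —
documented as SC+SR pooled — OSC, and their exact row-sum TOTAL).

Every analysis except the raw-count I/O runs on the depth-normalized
table: each sample is subsampled **without replacement** (multivariate
hypergeometric) to the minimum library size. Sampling with replacement
is available by flag; the without-replacement default is the standard
rarefaction reading of "normalize to the smallest library". Rarefaction
requires an explicit seed; the expected count of taxon *j* is `d·x_j/N`
(hypergeometric mean), which the tests verify by Monte Carlo.

## Index and test conventions

* **Chao1** is bias-corrected by default, `S_obs + F1(F1−1)/(2(F2+1))`
  (the classic `S_obs + F1²/(2F2)` by flag; it falls back to the
  corrected form when F2 = 0).
* **Simpson** is the finite-sample dominance `Σ n_i(n_i−1)/(N(N−1))` —
  the only form consistent with "most diverse group has the lowest
  Simpson"; `1−D` and `1/D` are trivial transforms left to the caller.
* **Shannon evenness** is `H/ln S_obs` with natural logs; for a
  single-taxon sample it is reported as missing (NaN), not 0.
* **Faith PD** includes the root path (rooted PD); an unrooted variant
  (branches with observed leaves on both sides only) is available.
* **Weighted UniFrac** is the normalized form
  `Σ_b L_b |p_A(b) − p_B(b)| / Σ_b L_b (p_A(b) + p_B(b))`, values in
  [0, 1]; the raw numerator by flag.
* **PCoA** eigendecomposes `−½ J D² J`. Negative eigenvalues are
  reported in the spectrum but carry no coordinates and are excluded
  from the proportion-explained denominator (Legendre convention).
* **ANOSIM** uses Clarke's statistic `R = (r̄_B − r̄_W)/(M/2)` with
  `M = n(n−1)/2` ranked distances, so perfect separation gives R = 1.
  p is the one-sided upper-tail permutation p with the +1 correction,
  `(1 + #{R* ≥ R})/(1 + n_perm)`, n_perm default 999, seeded. PERMANOVA
  (pseudo-F on squared distances) is provided as an alternative.
* **Spearman** ρ is tie-corrected (Pearson on midranks). Two-sided p is
  the exact permutation p for n ≤ 9 and the t approximation
  `t = ρ√((n−2)/(1−ρ²))` for larger n; at the survey's n = 12 the
  approximation applies. One consequence worth noting: a perfectly
  monotone pair at small n has the exact p `2/n!`, not 0.
* **Network edges** require |ρ| > 0.6 **and** p < 0.05 (both strict, no
  multiplicity correction — Benjamini–Hochberg by flag). Taxa present in
  fewer than `min_prevalence = 3` samples are excluded before
  correlation to avoid degenerate rank vectors; constant vectors yield
  missing ρ and never an edge. Isolated taxa are not network nodes.
* **Centralities** follow the conventions of interactive network tools
  on disconnected graphs: degree `k/(N−1)`; Brandes betweenness
  normalized by `(N−1)(N−2)/2`; closeness with the Wasserman–Faust
  within-component scaling `(N_c−1)/(N−1) · (N_c−1)/Σd`.
* **Hub rule**: degree centrality > 0.2, closeness > 0.35, betweenness
  > 0.35, all strict.
* **Modularity** is Louvain with an explicit seed; Q depends on the
  partition found, and the seed is recorded in the pipeline manifest.
* **Average path length** is the mean over connected pairs only; nodes
  of degree < 2 contribute 0 to the mean clustering coefficient.
* **Group comparisons** run Shapiro–Wilk on the one-way-ANOVA
  residuals; if rejected at 0.05 the compound is ln-transformed before
  ANOVA and Tukey HSD (an error suggests an offset when non-positive
  values make that impossible). Group means/SE are always reported on
  the original mg/g scale. The compact-letter display uses the
  insert-and-absorb algorithm; groups sharing a letter are not
  significantly different at 0.05.
* **Membership core**: taxa with count > 0 in *every* sample (the
  strictest reading of "common to all samples"; a per-group variant by
  flag), ranked by the mean of per-sample relative abundances (so deep
  samples do not dominate; pooled-count ranking by flag), ties broken
  lexicographically, truncated to top_n = 10. The combined core is the
  union with the hub core.

## The synthetic generator

`generate_community` draws per-taxon base log-abundances
`m_j ~ N(0, σ²)` with σ = 1.5, heavy-tailed enough that one or two
genera dominate each sample (dominant shares of 20–70% are typical, as
in real genus tables). Per sample, taxon log-abundance is
`m_j + τ·ε_js` with τ = 1.0; softmax gives the composition and counts
are realized multinomially at the configured depth (50,000 by default).

Correlation structure uses a Gaussian copula: a target Spearman ρ maps
to the latent Pearson correlation `r = 2 sin(πρ/6)`. Clique members
share a per-sample factor with loading √r; planted taxon–compound links
correlate the compound's latent Gaussian with the normal scores of the
taxon's relative abundance, so `assoc_rho = 1` with zero residual noise
yields exactly monotone (Spearman ±1) links. Compound magnitudes are
log-normal around typical QA scales (OMA 30, MA 5, SC 15, OSC 40 mg/g,
log-sd 0.6). Because the multinomial read-sampling and the compositional
closure perturb ranks, realized correlations match targets only
statistically; calibration tests assert the mean realized within-clique
ρ over 100 seeds is within ±0.15 of the target at depth 50,000
(measured ≈ 0.88 at a 0.95 target, ≈ 0.69 at 0.80).

An optional `group_sigma` (default 0, used at 0.8 by the demo analyses)
adds per-group latent shifts so ordination and ANOSIM see succession
structure; calibration and null measurements run with it off.

What the generator does **not** emulate: real tables are far sparser
(hundreds of genera, many zeros), so presence/absence features (Venn
uniqueness, prevalence filtering) are exercised mainly by crafted test
fixtures rather than the generator; there is no overdispersion beyond
multinomial sampling, no taxonomic correlation between the random tree
and the abundance structure, and no read-level noise (chimeras, OTU
clustering). Passing tests therefore demonstrate the correctness and
calibration of the machinery, not field realism.

A consequence of compositional closure worth knowing: proportions sum
to 1, so swings of dominant taxa induce weak positive correlation among
the remaining taxa. Under the default 60-taxon null community the edge
screen discovers ≈ 4.7% of pairs (below its nominal 5% level but above
the ≈ 4.2% iid rate); in small communities dominated by few taxa the
rate can exceed the nominal level. Relatedly, hub classification on a
planted-clique community has limited precision: within a clique all
shortest paths have length 1, so clique members acquire betweenness
only through noise edges that attach pendants to them, and the same
noise process creates spurious bridge nodes among the more numerous
background taxa. The planted cliques themselves are recovered reliably
as fully connected subgraphs (≈ 88% of seeds at ρ = 0.95).

## Reproducibility

The pipeline takes one global seed and fans it out to per-stage seeds
via `SeedSequence([seed, stage_index])` (synthesis, rarefaction, ANOSIM
permutations, Louvain), so stages can be re-run in isolation; the
manifest records the package version, all parameters, the per-stage
seeds and SHA-256 checksums of every output, and re-running with the
same configuration is byte-identical. Problem sizes used by the checks
in `scripts/acceptance.py`: 200 randomized instances per brute-force
oracle (graphs ≤ 9 nodes, trees ≤ 6 leaves, n ≤ 6 for exact-permutation
comparisons), 50 seeds for planted-clique recovery, 100 for association
power, 200 ANOSIM null runs at 999 permutations, and 50 seeds for the
null edge rate.
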