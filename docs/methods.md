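# Methods

## Moderated differential expression

Each dataset is a log2 expression matrix with a two-group (case/control)
design and no covariates. For feature *g*, the pooled sample variance s²_g
has d_g = n₁ + n₂ − 2 residual degrees of freedom. The hierarchical model
assumes the true variances follow a scaled inverse chi-square prior,
σ²_g ~ s₀²·d₀ / χ²(d₀), under which the posterior mean of σ²_g given s²_g
is s̃²_g = (d₀ s₀² + d_g s²_g)/(d₀ + d_g) and the moderated t-statistic
t_g = effect / √(s̃²_g (1/n₁ + 1/n₂)) follows a Student t distribution
with d₀ + d_g degrees of freedom under the null.

Hyperparameters are estimated by method of moments on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the equation
ψ′(d₀/2) = var(e) − ψ′(d_g/2) is solved by Newton inversion of the
trigamma function, and s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the
spread of log variances does not exceed the chi-square sampling noise
(var(e) ≤ ψ′(d_g/2)) the fit degenerates to d₀ = ∞, s₀² = exp(mean(e)),
i.e. complete shrinkage to a common variance. Features with non-positive
sample variance carry no log-variance information and are excluded from
the hyperparameter fit (they are still shrunk and tested — shrinkage
rescues zero-variance features). At least 10 usable features are
required. The implementation agrees with R limma's `eBayes` to ~1e−6 on
shared inputs (tested), but is written from the formulas above.

Limiting cases are exposed for verification: forcing d₀ = 0 reproduces
the ordinary pooled t-test; forcing d₀ = ∞ reproduces a z statistic with
the prior variance.

## Cross-dataset combination

Gene-level evidence from the regional datasets is combined per feature by
a signed-z Stouffer rule: zᵢ = sign(effectᵢ)·Φ⁻¹(1 − pᵢ/2) per dataset,
z_meta = Σ wᵢ zᵢ / √(Σ wᵢ²) with default weights wᵢ = √(dataset sample
size), two-sided p from z_meta, and Benjamini–Hochberg adjustment. This
rule was chosen because it handles unequal designs and features missing
from some platforms cleanly: a feature is combined over the datasets that
observe it (the count is reported), and features observed nowhere are
dropped with a logged count. Selection is strict: fdr < 0.01 for genes,
fdr < 0.05 for the single miRNA dataset (which needs no meta step — its
result is the moderated t plus BH).

BH adjustment is one shared implementation (step-up with monotonicity
enforcement) used by both the DE and enrichment stages, so identical
p-vectors give bit-identical adjusted values.

## Network construction

Interaction tables are typed miRNA→target edges (target class circRNA or
mRNA); identifiers are opaque, case-sensitive strings and a target may
carry only one class. Shared-miRNA counts for circRNA–mRNA pairs are
accumulated through an inverted index on the miRNA (per-miRNA cross
products of its circRNA and mRNA target lists), never an all-pairs scan,
so pairs with empty intersections cost nothing. A pair qualifies when it
shares at least `min_shared` miRNAs (default 5, a raw-count rule — no
overlap significance test is applied). The threshold is applied to
*pairs*; an interaction edge is retained exactly when it participates in
at least one qualifying (circRNA, miRNA, mRNA) triple. This closure makes
the network well defined and gives the monotonicity property that raising
the threshold never adds nodes, edges or triples. Crosstalk is
materialized per mediating miRNA (one triple per (pair, shared miRNA)),
which is the unit counted and ranked downstream. No expression
correlation between partners is used: circRNAs are not measured at all in
this design, and competition is inferred from shared regulators only.

## Disease subnetwork, risk flagging, ranking

A triple enters the disease subnetwork iff its mRNA is a CDEG **or** its
miRNA is a DEmiR; the subnetwork is rebuilt from retained triples with the
same closure rule, so risk ⊆ disease ⊆ full triples nests node- and
edge-wise. Risk flagging is applied *after* disease extraction: a disease
triple is a risk crosstalk iff it contains a curated known disease gene
or miRNA. circRNAs are ranked by raw risk-crosstalk count, ties broken by
ascending id for reproducibility; a normalized coverage column
(risk/total crosstalks per circRNA) is emitted as an auxiliary view but
never drives the rank. circRNAs themselves are never tested for DE or
known-disease membership — no circRNA expression or curated circRNA list
exists in this design.

## Degree distribution

Degrees pool all three node classes. The power-law exponent is the
continuous MLE α = 1 + n/Σ ln(xᵢ/xmin) over degrees ≥ xmin (default 1),
plus an OLS fit of log(count) on log(degree) whose R² summarizes
straightness of the log-log histogram. These are diagnostics, not
goodness-of-fit tests; xmin selection à la Clauset–Shalizi–Newman is out
of scope. The MLE is exact for its own generative model (continuous
Pareto tail); on integer-valued degrees with xmin = 1 it is known to be
upward-biased, which is acceptable for the qualitative scale-free check
it supports. The recovery test therefore draws from the continuous model.

## Over-representation analysis

For query size n, term size K, overlap k in a universe of N genes, the
p-value is P(X ≥ k), X ~ Hypergeometric(N, K, n) (SciPy's survival
function), BH-adjusted across all terms with K ≥ 1 after universe
intersection, sorted by (p, term id). The background universe dominates
ORA results, so it is explicit and logged: the pipeline default is every
mRNA id appearing in the interaction tables. (A "network mRNAs" policy
exists but degenerates on the synthetic study, where the network's mRNA
set nearly equals the query; with real interaction snapshots, where
thousands of pairs qualify, either choice is sensible.) A `file` policy
accepts a user-supplied universe.

Calibration of the discrete test is assessed with exact randomized
p-values u = P(X > k) + U·P(X = k), U ~ Uniform(0,1), which are exactly
uniform under the null; the raw discrete p-values are super-uniform
(conservative) and would fail any literal uniformity test on small
overlaps.

## Synthetic-data generator

The generator is the package's test bed: it emulates the study design the
pipeline assumes and nothing more.

* **Expression.** Six gene datasets of 8 + 8 samples over 1,500 features
  (the miRNA dataset: 4 + 4 over 200 miRNAs, matching a typical small
  miRNA microarray); per-feature variances drawn per dataset from the
  scaled inverse chi-square prior with defaults d₀ = 4, s₀² = 0.05; DE
  fraction 0.10 with log2 effect magnitude ~ N(1.0, 0.3²) redrawn per
  dataset and sign fixed per feature (the meta-analysis looks for
  cross-region consistency, so membership and direction are shared while
  magnitudes are heterogeneous). Effect and noise magnitudes are package
  defaults chosen to be realistic for log2 microarray data, not values
  taken from any particular study.
* **Interactions.** 12 planted circRNAs × 4 pairs each, every pair
  sharing a pool of 6 miRNAs drawn from a 200-miRNA universe, over a
  background of independent edges at probability 0.01. The miRNA universe
  is large enough that independent pools rarely overlap by ≥ 5, so
  planted pairs are the only qualifying ones in expectation. All planted
  circRNAs get identical structure so that the risk ranking is driven by
  the curated lists, not by degree.
* **Known lists.** 27 known genes / 45 known miRNAs (sizes of typical
  curated disease lists). The designated risk circRNA's partner mRNAs are
  placed in the known-gene list, giving it full risk coverage; the
  remainder is random, with a deterministic resampling guard that keeps
  the risk circRNA strictly dominant in the planted truth.
* **Gene sets.** 50 random terms of 40 genes over the 500-mRNA universe
  plus one planted term containing all planted-pair mRNAs and 10 extras.
* **DE/planting coordination.** The DE feature set contains the planted
  pairs' mRNAs first, then random fill — planted crosstalks must survive
  disease extraction for recovery to be measurable.

All components draw from independent substreams of one seed
(`SeedSequence(seed, spawn_key=(component,))`), so regenerating one
component never shifts another and every output is byte-identical across
runs with the same seed.

What the generator does **not** model: probe-level noise, batch effects,
normalization artifacts, correlated genes, brain-region biology, or
realistic interaction-database topology. Passing tests therefore
demonstrate correctness and calibration of the *methods* under their own
assumptions, not performance on real microarray data.

## Numerical and design notes

* Trigamma inversion: Newton iteration with limma-style initialization
  x₀ = 0.5 + 1/y; converges to ~1e−12 relative.
* p-values are clipped at 1e−300 before Φ⁻¹ to avoid infinities in the
  Stouffer transform.
* Strict inequalities at every FDR threshold.
* Empirical FDR under the global null is measured as the mean over seeded
  replicates of V/max(R, 1) (equivalently, the fraction of replicates
  with any discovery, since every discovery is false under the null).
* The file pipeline writes deterministic artifacts (sorted rows, sorted
  JSON keys, no timestamps); manifests carry SHA-256 checksums of every
  output, so identical configuration + seed reproduce identical
  checksums.
* Degenerate inputs have defined behavior throughout: empty interaction
  files warn, empty annotation sets yield empty (not failing)
  subnetworks, all-equal degrees make the power-law exponent an explicit
  error, and an all-zero-variance matrix makes prior estimation fail with
  a message naming the minimum feature count.

## Known limitations

* The Stouffer weights are √(sample size); no inverse-variance or
  effect-size meta-analysis is offered.
* ORA ignores gene-set redundancy and annotation DAG structure.
* The power-law diagnostic has no alternative-model comparison.
* Two-group designs only; no covariate adjustment, paired designs or
  multi-level factors.
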