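# Methods

`guttide` reimplements, as a tested reusable pipeline, the downstream
statistical analysis of a multi-site gut-microbiome time course: alpha and
beta diversity with permutation tests, a null-model decomposition of
community-assembly processes, SparCC co-occurrence networks with module and
node-role analysis, and taxon–covariate association. Because the raw
sequencing data behind such studies require a heavyweight upstream
(denoising, taxonomy, tree building) that is out of scope here, every stage
is exercised against a synthetic-data generator with recorded ground truth,
and validation is property-based: exact oracle agreement, statistical
calibration, and recovery of planted structure.

## Diversity and ordination

Alpha diversity is Shannon entropy in nats, observed ASV richness, and
Pielou evenness J = H / ln S (undefined, reported as missing, for
single-taxon samples). Natural logs make J = H / ln S exact.

Between-sample structure uses the Aitchison geometry: a uniform pseudocount
of 1 is added to all counts (the zero-replacement rule is a config knob),
rows are centered log-ratio (CLR) transformed, and the Euclidean distance
between CLR vectors is the Aitchison distance. PCoA is the classical Gower
eigendecomposition of the double-centered −D²/2 matrix; because the
Aitchison distance is Euclidean-embeddable, negative eigenvalues can arise
only from numerics, so they are clamped to zero and excluded from the
proportion-explained denominator. A cross-check test verifies that PCoA of
the Aitchison distance agrees with PCA of the CLR matrix and with
scikit-bio's implementation.

Group differences are tested with one-way PERMANOVA and ANOSIM (seeded
permutation tests, p = (hits + 1)/(permutations + 1), default 999
permutations) and alpha diversity with the two-sided Wilcoxon rank-sum test
(exact null for combined n ≤ 20 without ties, normal approximation with tie
correction otherwise). Permutations are free (unrestricted): the study
design has repeated measures within animals, and a restricted
(within-animal) permutation scheme would be the conservative alternative;
this caveat is deliberate and documented rather than hidden.

## Community assembly (βNTI + RCbray)

Turnover between two communities is decomposed into five ecological
processes with the standard two-step null-model framework:

1. **βMNTD / βNTI.** βMNTD is the abundance-weighted mean distance from
   each taxon to its nearest relative in the other community,
   ½[Σ_k f_k·min_m d(k,m) + Σ_m f_m·min_k d(m,k)], with patristic distances
   from the rooted tree (an unweighted variant is available behind a flag).
   The null shuffles taxon identities across all tips of the tree
   (equivalently, permutes rows and columns of the patristic matrix) and
   recomputes βMNTD, by default 999 times; βNTI is the resulting z-score.
   Pairs with a degenerate null (sd = 0, e.g. compositionally identical
   samples) are flagged and excluded from the fractions.
2. **Raup–Crick on Bray–Curtis.** For pairs not attributed to selection,
   null communities preserve each sample's observed richness and total
   abundance: taxon identities are drawn without replacement with
   probability proportional to occupancy (implemented as exact Gumbel
   top-k weighted sampling), each drawn taxon is seeded with one
   individual, and the remaining abundance is allocated multinomially in
   proportion to the pooled metacommunity relative abundances.
   RC = 2·[P(B_null < B_obs) + ½P(B_null = B_obs)] − 1 ∈ [−1, 1].

Classification per pair: βNTI > +2 variable selection; βNTI < −2
homogeneous selection; otherwise RC > +0.95 dispersal limitation,
RC < −0.95 homogenizing dispersal, |RC| ≤ 0.95 drift. The ±2 and ±0.95
thresholds follow the established convention and are exposed in config.
Pairs are computed within site by default, matching the per-site reporting
of the study design. Fractions always sum to 1 over classified pairs.

Within-null-iteration draws are shared across pairs (one set of null
communities per iteration), which is the standard vectorization and does
not change per-pair marginal null distributions.

A calibration note: the RCbray null estimates occupancy and metacommunity
profiles from the analyzed table itself. On data generated by the null
recipe with known parameters, this self-estimation leaves a
realization-dependent bias in the RC mean (up to ≈0.3 at 16–40 samples)
even though the overwhelming majority of pairs stay inside the drift band
|RC| ≤ 0.95. Tests therefore assert the classification-level property, not
a tight bound on the mean.

## SparCC

Counts are compositional, so SparCC works in log-ratio space: for taxa i, j
the log-ratio variance t_ij = var(ln x_i/x_j) relates to latent basis
variances ω and correlations ρ by t_ij = ω_i + ω_j − 2ρ_ij√(ω_iω_j). Under
the sparsity approximation Σ_j ρ_ij ≈ 0 the row sums give a linear system
t = M ω with M = 11ᵀ + (D−2)I, solved directly. The strongest pair above
the exclusion threshold (default 0.1) is then removed from the system and ω
re-solved, up to 10 rounds; a taxon left with fewer than three active
partners is dropped entirely (its correlations are reported missing and the
taxon flagged) — without this component-exclusion step small systems go
singular. Negative basis variances are clamped at a small floor and
flagged; ρ is clipped to [−1, 1].

Fractions are estimated Bayesianly: each of 20 inner iterations draws
per-sample fractions from Dirichlet(counts + 1) and the per-iteration ρ
estimates are averaged. Setting the inner iteration count to 0 selects the
deterministic plug-in (posterior-mean) fractions, used by the
scale-invariance test.

Pseudo-p-values use a permutation null by default: each taxon's counts are
permuted independently across samples (destroying all inter-taxon
association while preserving marginals), SparCC is re-run per iteration,
and p = (#{|ρ_null| ≥ |ρ_obs|} + 1)/(n + 1), two-sided, 1,000 iterations by
default. Because the literature's "bootstrap" wording is ambiguous, a
sample-resampling bootstrap (sign-stability pseudo-p) is available behind
`null="bootstrap"`.

## Networks, modules, roles

Network edges require p < 0.01 (strict) and |ρ| ≥ 0.6 (inclusive);
isolated nodes are dropped. Transitivity is the binary global clustering
coefficient, 3·triangles / connected triples. Louvain modularity
maximization runs on absolute correlation weights (standard modularity
requires non-negative weights; signs are kept for roles and reporting),
with the partition taken from the best of 10 seeded restarts by Q, since
Louvain is visit-order dependent. Major modules are those with strictly
more than 20 nodes.

Each connected node gets one of four interaction roles from two fractions:
intra_fraction (edges inside its own module / degree) and positive_fraction
(positive edges / degree). "Intramodule" iff intra_fraction > 0.5, else
"intermodule"; "friendly" iff positive_fraction > 0.5, else "competitive";
exact ties resolve to intermodule/competitive. This decision rule is the
package's own deterministic reading of a degree-proportion partition — the
original supplementary rule it stands in for is not recoverable — and is
therefore exposed so an alternative rule can be swapped in.

## Association

Taxa are filtered before correlation: retained taxa need mean relative
abundance ≥ 0.01% AND occupancy ≥ 0.5 (both boundaries inclusive).
Spearman rank correlations (average-rank ties; exact enumeration p for
n ≤ 10 without ties, t-approximation otherwise) are computed per
(taxon, covariate) pair at ASV level by default (genus aggregation
available), and Benjamini–Hochberg adjusted per covariate column across
taxa (a global family is available) — the per-column family matches the
one-star-per-cell heatmap convention.

Envfit regresses each centered covariate on the first two PCoA axes
(axis count configurable); R² is the squared multiple correlation and the
permutation test shuffles the covariate across samples,
p = (hits + 1)/(n_perm + 1). The pipeline fits covariates both on the
all-sample ordination (where the site gradient dominates) and within each
site.

## Synthetic-data generator

The generator emulates the study design — 9 animals × 4 timepoints
(1W, 2W, 1M, 2M) × 3 digestive-tract sites (oral cavity, rumen, feces),
108 samples — with every latent quantity recorded for recovery tests.

**Phylogeny and traits.** A pure-birth (Yule) tree over the ASVs, rescaled
to unit root-to-tip depth. A single niche trait evolves by Brownian motion
whose rate decays with time (early-burst, rate ∝ e^(−2t) by default):
this front-loads divergence onto deep branches so clades are conserved in
their trait, which is what makes niche filtering phylogenetically
detectable. Tip traits are z-scored so optima are in trait-sd units.
Taxonomy (phylum…genus) is derived by cutting the tree into nested
monophyletic clades, so phylum labels in networks are meaningful.

**Communities.** The metacommunity profile π is log-normal (σ = 2).
Each sample is built sparsely, mirroring real amplicon occupancy
structure: richness is drawn log-normally around 25% of the pool, taxon
identities are drawn without replacement with weights π^0.6 (the flattened
occupancy–abundance relationship of real surveys), and abundances follow a
regime-shaped profile; counts are multinomial at a log-normal depth
(mean ≈ 70,000, log-sd 0.14, echoing reported depth dispersion), so each
sample's counts sum exactly to its drawn library size. The sparsity is
essential: with near-complete per-sample richness the Raup–Crick null has
no identity-draw variance and every regime degenerates to "dispersal
limitation".

Per-regime mechanisms (defaults in parentheses):

- **drift** — neutral identity draws, abundance noise LN(0.3): turnover
  comparable to the Raup–Crick null.
- **selection** — a Gaussian niche filter exp(−(trait−opt)²/2σ²)
  (σ = 0.25) multiplies both identity and abundance weights; taxa below a
  viability floor (0.01) are pruned, so selection reduces richness rather
  than padding communities with far-from-optimum taxa. Each animal's
  micro-environment sits at one of the two opposing tail optima ±opt
  (opt = 2 trait sd recommended), so same-optimum pairs show homogeneous
  selection (βNTI < −2) and opposite-optimum pairs variable selection
  (βNTI > +2) — the framework reports their sum as one "selection" slice.
  As σ → ∞ the regime degenerates exactly to drift (tested by KS on βNTI).
  The within-site optimum variation across animals is a deliberate design
  choice: with one site-wide optimum the variable-selection branch of the
  framework would never be exercised.
- **dispersal_limitation** — per-animal log-offsets u ~ N(0, 3²) damped by
  migration m = 0.01 act on the abundance profile (π·e^((1−m)u)) while
  occupancy stays core-like: host lineages drift apart in which taxa
  dominate, exactly the divergence the pooled-metacommunity Raup–Crick
  null cannot reproduce, with no phylogenetic structure.
- **homogenizing_dispersal** — mass effects: a fraction m = 0.9 of each
  sample's richness is one shared site-level identity set (the top taxa by
  π), transient immigrants arrive damped by (1−m), and abundance noise is
  only LN(0.05), leaving samples far more similar than null draws.

The default study assigns drift to the oral cavity, dispersal limitation
to the rumen, and homogenizing dispersal to feces, echoing the dominant
per-site signal the framework typically reports for these sites.

**Planted correlations.** Pairs of taxa are rewired by replacing their
log-basis abundances with a bivariate normal of correlation ρ (default 8
pairs at ρ = 0.8, marginal log-sd 0.5) before multinomial sampling. Pair
members are drawn from the 70th–95th abundance percentile: abundant enough
that count-level noise does not drown the signal after prevalence
filtering, rare enough that the planted fluctuations do not perturb
community-level turnover statistics.

**Covariates.** Sixteen covariates (six VFAs plus their sum and the
acetate:propionate ratio; eight blood parameters) are generated
log-linearly from the site and time gradients with recorded loadings and
realistic baselines/units (e.g. acetate ≈ 60 mmol/L, total protein
≈ 70 g/L). TP, P and Tbil load strongly on the site gradient and Ca, TG
and VAL moderately — the planted envfit signal. TVFA is exactly the
component sum (validated on read).

**What the generator does not emulate.** Sequencing error and chimeras,
compositional count overdispersion beyond the multinomial, real taxonomic
label structure, temporal autocorrelation within animals beyond the
animal-level offsets, and any real covariate–taxon causal coupling (the
within-site envfit signal is null by design; the covariates track the
between-site gradient). Passing recovery tests therefore demonstrates
correctness of the estimators under the stated generative assumptions, not
performance on real amplicon data.

## Numerical choices and problem sizes

- Permutation p-values are always (hits + 1)/(permutations + 1); seeded
  generators spawn per-stage streams from one global seed
  (`numpy.random.SeedSequence`), making full pipeline outputs
  byte-identical under a fixed seed.
- βNTI uses a streaming (Welford) mean/sd over null iterations; RCbray
  ties count one half.
- The test suite and the acceptance script run the stochastic validations
  at reduced but statistically adequate sizes chosen once: 500 null
  replicates for each type-I-error check; 100 independent community pairs
  × 999 nulls for the βNTI null moments; 10 replicates per assembly regime
  at 500 ASVs and 12 samples with 199 nulls; SparCC accuracy at 50 taxa ×
  200 samples; the end-to-end study at full design size (108 × 500) with
  99–199 null/bootstrap iterations.
- Default analysis parameters follow the study conventions: 999
  permutations/nulls, 1,000 SparCC bootstrap iterations, network
  thresholds p < 0.01 and |ρ| ≥ 0.6, prevalence filter 50%, major-module
  cutoff > 20 nodes.

## Known limitations

- One-way PERMANOVA/ANOSIM only; no repeated-measures/strata permutation.
- The SparCC exclusion path reports unidentifiable taxa as missing rather
  than attempting a reduced re-estimate of their pairwise correlations.
- The node-role rule is a declared convention, not an inference of the
  original study's unpublished rule.
- Rarefaction, UniFrac, per-clade (iCAMP-style) assembly binning and
  phylogenetic-signal testing of traits are out of scope.
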