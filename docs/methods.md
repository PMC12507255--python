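# Methods

This note documents the statistical models implemented in `haplotrait`,
the synthetic data they are exercised on, the numerical choices made where
the design was genuinely open, and the limits of what the package's tests
establish. No empirical number is stated here that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Two-way admixture simulation for ancestry-specific effect sizes

### Generative model

For a diploid cohort of N individuals, each haplotype copy d ∈ {1, 2} of
individual i receives:

1. a **latent ancestry** Ã_i1d ~ Bernoulli(a), with Ã_i2d = 1 − Ã_i1d,
   where a is the expected ancestry-1 fraction;
2. a **call certainty** p_id ~ Beta with mean p and variance (0.05/p)²,
   obtained by moment matching (α = pν, β = (1−p)ν with
   ν = p(1−p)/Var − 1). The certainties are calibrated by construction:
   the observed ancestry-1 probability is p_i1d = p_id if Ã_i1d = 1 and
   1 − p_id otherwise;
3. a **true ancestry call** A*_i1d ~ Bernoulli(p_i1d), A*_i2d = 1 − A*_i1d;
4. a **genotype** under the Balding–Nichols model: the ancestral
   risk-allele frequency f is uniform on a MAF bin, the two population
   frequencies are f_k ~ Beta(f(1−F_st)/F_st, (1−f)(1−F_st)/F_st)
   restricted to the same bin by rejection sampling (cap 10,000 tries),
   and G_id ~ Bernoulli(f_k) with k the true ancestry of the copy;
5. a **phenotype** Y_i = 2 + 5·T_i1 + 1·T_i2 + ε_i with
   ε ~ N(0, 15²) and T_ik = Σ_d G_id A*_ikd the true ancestral dosages.
   The noise SD is deliberately large: a single SNP explains very little
   trait variance in practice.

Defaults mirror the reference study conditions: N = 20,000,
a ∈ {0.1, 0.25, 0.5}, p ∈ {0.5, …, 0.98}, F_st = 0.2, MAF bins
[0.01, 0.05], [0.05, 0.10], [0.10, 0.20], [0.20, 0.50], 1,000 replicates.
The MAF bins are applied directly to the risk-allele frequency (no folding
at 0.5); the top bin is [0.20, 0.50].

Two documented edge conventions: p = 1 is handled as a point mass (the
variance rule admits no proper Beta there), and p close to but below 1
(e.g. 0.999) is rejected with an explicit error because
(0.05/p)² ≥ p(1−p). The Beta draw for p_id is **not** truncated to
[0.5, 1]; values below 0.5 are possible and make the thresholded
representation wrong by design.

### The four ancestry representations

Dosages are rebuilt from the same cohort under four substitutions of the
per-copy ancestry weight A_ikd in T_ik = Σ_d G_id A_ikd,
X_i1 = Σ_d A_i1d:

- **TRUTH** — the true one-hot calls A*;
- **RAW** — the observed probabilities p_ikd as weights;
- **BESTGUESS** — 1{p_ikd ≥ 0.5}; the tie at exactly 0.5 resolves to
  ancestry 1, following the defining inequality (asymmetric, hence
  documented);
- **SAMPLING** — one Bernoulli(p_i1d) draw per copy. One draw is taken
  per dosage construction; averaging over many draws happens at the level
  of fitted effect sizes across replicates, not by averaging dosages
  (a configurable count is unnecessary for the estimation contrasts the
  grid reports).

Every scheme conserves mass: T_i1 + T_i2 equals the individual's
risk-allele count exactly (to 1e-10 in floating point for RAW).

### Regression and grid

The Tractor model Y = β0 + β1·T1 + β2·T2 + β3·X1 (+ covariates) is fit by
OLS via a QR-based solver with classical standard errors
σ̂²(DᵀD)⁻¹ (σ̂² the residual mean square). A rank pre-check rejects
singular designs naming the collinear column — e.g. X1 constant when all
copies share one ancestry — and `run_grid` excludes such replicates with a
surfaced counter rather than regularizing.

Grid replicates redraw everything; the cohort is shared across schemes
within a replicate so scheme contrasts are paired (this only reduces
comparison variance). Child RNG streams derive deterministically from
(master seed, cell index, replicate index) via `numpy` `SeedSequence`, so
any replicate is reproducible in isolation.

Problem sizes used in the shipped checks: effect-size recovery at
n = 5,000 with 200 replicates (reference cell a = 0.5, p = 0.9, MAF
[0.20, 0.50]); the representation-ordering grid at n = 2,000 with 100
replicates over a ∈ {0.1, 0.5} × p ∈ {0.7, 0.98} × two MAF bins. These
are the package's chosen study sizes; Monte-Carlo standard errors are
computed and asserted against, so conclusions do not depend on the
full-scale run.

## 2. Ancestral risk scores

### Score

Given painting probabilities A_ijk (haplotype i, SNP j, ancestry k),
binary risk alleles G_ij and per-SNP effects β_j, the ancestry-specific
risk-allele frequency is the painting-weighted mean
f_jk = Σ_i A_ijk G_ij / Σ_i A_ijk, and ARS_k = Σ_j f_jk β_j over the M
pruned trait-associated SNPs. Mass conservation
Σ_k f_jk (Σ_i A_ijk) = Σ_i G_ij holds per SNP, and a fully hard-called
painting reduces f_jk to the within-ancestry sample frequency. LD pruning
is an upstream filter: the module accepts a precomputed keep-list, with a
greedy genotype-r² utility (threshold 0.5) provided for synthetic data
only. Effect sizes are accepted as input; estimating them from phenotypes
is out of scope.

### Uncertainty and test

- **Individuals.** Bootstrap over individuals (1,000 resamples by
  default; both haplotypes of an individual move together, implemented as
  multinomial weights). The 2.5%/97.5% frequency quantiles f_jk^lower/upper
  substituted into the score give the reported interval — the defining
  construction, which is order-inconsistent when some β_j < 0; a
  percentile interval on the bootstrap score replicates is available via
  `ci_method="percentile"` without asserting which convention is
  preferable. σ(ARS_k) is the SD of the bootstrap score replicates (the
  definition names only "standard error obtained by bootstrap").
- **SNPs.** Each trait SNP is matched to pool SNPs whose genome-wide
  risk-allele frequency rounds (half-even) to the same 1% bin; pseudo-
  scores ARS*_k = Σ_j f*_jk β_j are built by resampling matched SNPs with
  replacement (50,000 draws by default) keeping the real β_j. The matched
  pool is pruned once up front, not per draw. A zero-weight ancestry, an
  empty match set, or an infeasible configuration raises a named error.
- **Test.** Each pseudo-score is inflated with N(0, σ(ARS_k)²) noise and
  p_k = 2·min(prop(≥ obs), prop(≤ obs)), capped at 1 — two-sided and
  symmetric around the observed value (measuring extremeness relative to
  the weighted mean is a defensible alternative; the observed-value
  convention is used and stated). p_k = 0 at the empirical resolution is
  clipped to 2/n_draws (with a warning) before Fisher's method
  χ²_{2K} = −2Σ ln p_k. Benjamini–Hochberg correction is applied in two
  separate families: across the K ancestries within a phenotype, and
  across phenotypes for the Fisher-combined values.
- The population-size-weighted mean score uses weights proportional to
  total genome-wide (pool) painting mass per ancestry; weights sum to 1.

### What the synthetic painted cohort emulates

Individuals get Dirichlet(1) global ancestry proportions; each
haplotype-SNP draws a latent ancestry from them and a calibrated
probability vector concentrated on it (Beta-distributed confidence, mean
0.9 by default, remainder spread evenly). Every SNP — trait and pool —
carries genuine per-ancestry differentiation: Balding–Nichols frequencies
around its genome-wide frequency with a background F_st of 0.1
(continental scale). The null scenario (δ = 0) therefore means trait SNPs
carry no ancestry signal *beyond the genome-wide background*, which is
the hypothesis the matched resampling tests; the alternative adds δ_k to
ancestry k's frequency at trait SNPs.

Two generator properties matter for the test's behaviour and were chosen
deliberately:

- the pool must be genome-wide-like: with too few pool SNPs each 1% bin
  holds only a handful of candidates, pseudo-scores resample from
  too-narrow finite sets, and the test becomes sharply anti-conservative.
  The default pool of 3,000 SNPs uniform on [0.01, 0.99] (~30 per bin)
  restores the intended regime;
- background differentiation must dominate frequency-estimation noise,
  as it does at biobank scale; without it the σ-inflation step doubles
  the null variance and the test is badly conservative.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (paintings and genotypes are independent across SNPs, so the LD
pruning contract is exercised only structurally), admixture-LD tracts,
painting error that is *mis*-calibrated, and effect-size estimation
error. Calibration and power results on this cohort therefore speak to
the test's resampling logic under calibrated painting, not to robustness
against those real-data features.

The shipped calibration experiment uses K = 3 ancestries, N = 150
individuals, M = 30 trait SNPs, pool 3,000, reduced bootstraps 200/5,000,
with 1,000 null phenotype replicates (rejection rate at 5% asserted
within binomial 95% bounds, plus a loose Kolmogorov–Smirnov uniformity
check) and 200 replicates under δ = (0.2, 0, 0) for power. Reducing the
bootstrap counts perturbs p-values only within resampling noise (rank
correlation > 0.95 on a fixed cohort), which justifies the reduced
defaults in the experiments.

## 3. Loadings and localization diagnostics

For sample-by-SNP genotypes X (column-centered; centering is applied
before both computations so the two loading sets are comparable) and a
component matrix H, the projected loadings are the least-squares solution
V_h = ((HᵀH)⁻¹HᵀX)ᵀ, leaving residuals orthogonal to H (asserted to
1e-8); rank-deficient H raises. Principal-component loadings are the top
right-singular vectors of X.

Localization: each component's absolute loadings are scaled to unit
Euclidean norm (so differently scaled loading sets share a scale), the
lag-1 autocorrelation uses the standard biased (divide-by-n)
autocovariance estimator — no estimator is canonical here and the biased
one is the common default — and genome profiles sum the scaled absolute
loadings over consecutive 100-SNP bins (a trailing partial bin is kept).
A component concentrated in a contiguous block scores high lag-1 ACF; a
genome-wide diffuse component scores near zero. Per-component values are
emitted and any averaging (over components or chromosomes) is left to the
caller. Sign flips of a component change nothing, and constant or
all-zero absolute loadings raise a zero-variance error.

## 4. Input/output and reproducibility conventions

All tables are UTF-8 TSV with headers, floats at 10 significant digits
(written atomically and round-tripping exactly at that precision).
Configurations are YAML/JSON mirroring the dataclass field names. Every
CLI run writes a manifest (config hash, seed, library versions). All
randomness flows from the master seed; no operation reads ambient
entropy. The educational-attainment recoding maps the seven qualification
category labels onto the years-of-education scores {7, 10, 13, 15, 19,
20} by exact string match after whitespace normalization (two category
labels share the score 10; no fuzzy matching).

## 5. Known limitations

- The admixture simulation is single-SNP per replicate and strictly
  two-way; K > 2 Tractor dosages and logistic (binary-trait) Tractor are
  not implemented.
- The painted-cohort generator has no LD, so the frequency-matched null's
  "LD-pruned pool" aspect is exercised through the pruning hook, not
  through realistic correlation structure.
- The paper-literal score interval is not order-safe under negative
  effects (see above); both conventions are exposed.
- The empirical test's p-values are discrete at resolution 2/n_draws;
  Fisher aggregation clips zeros to that resolution, which is
  conservative for extremely significant ancestries.
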