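# haplotrait

Local-ancestry-aware association analyses for admixed cohorts: a tested
implementation of (i) the simulation study showing when ancestry-specific
GWAS effect sizes are recoverable under uncertain local ancestry
inference (LAI), (ii) ancestral risk scores (ARS) with two-layer
uncertainty quantification and a non-parametric significance test, and
(iii) loading/autocorrelation diagnostics that separate population-
structure components from components tagging localized LD.

## Who this is for

Statistical geneticists working with admixed cohorts who want to (a)
quantify how LAI uncertainty propagates into Tractor-style
ancestry-specific effect-size estimates before trusting them on real
data, (b) attribute a polygenic signal to ancestries through
painting-weighted allele frequencies with honest uncertainty, or (c)
check whether an embedding component reflects genome-wide structure or a
single genomic region. Real data (genotypes, painting probabilities,
effect sizes) enter as plain TSV matrices; everything is also runnable
end to end on the package's own synthetic cohorts.

## The models

**Tractor regression.** At a SNP in a two-way admixed cohort, with
`T_k` the ancestry-k risk-allele dosage and `X_1` the ancestry-1 locus
count,

    Y = β0 + β1·T1 + β2·T2 + β3·X1 + Σ_j β_{j+3} C_j + ε.

The simulation generates cohorts with latent ancestry (admixture
fraction `a`), calibrated per-haplotype call certainties (Beta with mean
`p`, variance `(0.05/p)²`), Balding–Nichols genotypes (F_st = 0.2 within
a MAF bin) and phenotype `Y = 2 + 5·T1 + 1·T2 + ε`, `ε ~ N(0, 15²)`,
then fits the model with dosages built from four ancestry
representations — TRUTH, RAW (probability weights), BESTGUESS
(thresholded), SAMPLING (drawn calls) — over a grid of `a`, MAF bin and
certainty.

**Ancestral risk score.** With painting probabilities `A_ijk` and risk
alleles `G_ij`,

    f_jk = Σ_i A_ijk G_ij / Σ_i A_ijk,      ARS_k = Σ_j f_jk β_j.

Uncertainty over individuals comes from a bootstrap (frequency quantile
bands, score intervals, σ(ARS_k)); uncertainty over which SNPs are
trait-associated comes from a frequency-matched null that resamples each
trait SNP among pool SNPs with the same genome-wide frequency (1% bins).
The empirical test inflates null draws with N(0, σ²) noise, doubles the
smaller tail, and aggregates across ancestries with Fisher's method and
Benjamini–Hochberg correction.

**Loadings diagnostic.** `V_h = ((HᵀH)⁻¹HᵀX)ᵀ` projects a component
matrix onto genotypes; PC loadings come from the SVD of X. The lag-1
autocorrelation of unit-normalized absolute loadings along the genome,
plus 100-SNP binned profiles, flags components that tag localized LD.

## Worked example

```python
import numpy as np
from haplotrait import (AdmixtureSimConfig, ARSSimConfig, AncestralRiskScore,
                        generate_painted_cohort, run_grid)

# 1. Effect-size recovery: TRUTH vs thresholded calls at 70% certainty
cfg = AdmixtureSimConfig(n_individuals=2000, n_replicates=100, seed=42)
grid = run_grid(cfg, schemes=("TRUTH", "BESTGUESS"), p_values=[0.7])
print(grid[["scheme", "p", "mean_beta1", "mean_beta2", "mc_se_beta1"]])

# 2. ARS on a painted cohort whose ancestry-1 trait-SNP frequencies are
#    shifted by +0.2 (ancestries 2 and 3 are null)
cohort = generate_painted_cohort(ARSSimConfig(
    n_individuals=200, n_ancestries=3, n_trait_snps=30,
    delta=(0.2, 0.0, 0.0), seed=9))
model = AncestralRiskScore(n_boot_individuals=500, n_boot_snps=10_000,
                           random_state=9).fit(cohort)
print(model.summary())
```

Output:

```
   scheme   p  mean_beta1  mean_beta2  mc_se_beta1
    TRUTH 0.7    5.008413    0.947226     0.068232
BESTGUESS 0.7    3.716581    2.237576     0.081575

 ancestry      ars   ci_low  ci_high    sigma  p_empirical   p_bh
ancestry1 2.030824 1.851578 2.204558 0.021364       0.0000 0.0000
ancestry2 1.518177 1.325624 1.709238 0.021263       0.0036 0.0054
ancestry3 1.590665 1.392545 1.797154 0.024291       0.0498 0.0498
```

With true ancestry calls the generative effects (5, 1) are recovered to
within Monte-Carlo error; thresholding 70%-certain calls drags β̂1 toward
β̂2 (3.72 vs 2.24) — ancestry-specific effects are no longer separately
identifiable. In the ARS run, the shifted ancestry's score (2.03) sits
far outside its frequency-matched null (p below the 2/10,000 empirical
resolution, printed as 0), while the other two ancestries are marginal;
`ci_low`/`ci_high` bound the score against resampling of individuals and
`sigma` is its bootstrap standard error.

A command-line interface mirrors the library:

```sh
haplotrait tractor-grid --config grid.yaml --seed 1 --out grid.tsv
haplotrait make-cohort  --config cohort.yaml --out cohort/
haplotrait ars-test     --cohort-dir cohort/ --seed 1 --out ars.tsv
haplotrait loadings-acf --genotypes X.tsv --components H.tsv --out-prefix lo
```

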