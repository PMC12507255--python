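"""Ancestral risk scores with two-layer uncertainty and significance testing.

An ancestral risk score (ARS) attributes a polygenic signal to ancestries
in an admixed cohort.  With painting probabilities ``A_ijk`` (haplotype i,
SNP j, ancestry k) and binary risk-allele indicators ``G_ij``, the
ancestry-specific risk-allele frequency of SNP j is the painting-weighted
mean

    f_jk = sum_i A_ijk G_ij / sum_i A_ijk,

and the score for ancestry k over M pruned trait-associated SNPs is

    ARS_k = sum_j f_jk beta_j.

Two sources of randomness are quantified.  Randomness over which
individuals were sampled is handled by bootstrapping individuals (both
haplotypes move together) to obtain frequency quantile bands, score
confidence bounds and the score's bootstrap standard error sigma_k.
Randomness over which SNPs happen to be trait-associated is handled by a
frequency-matched null: each trait SNP is matched (genome-wide frequency
rounded to 1%) to trait-unassociated pool SNPs, and pseudo-scores are
built by resampling matched SNPs with replacement while keeping the real
effect sizes.  The empirical test inflates each null draw with Gaussian
noise of SD sigma_k and doubles the smaller tail proportion; per-ancestry
p-values are combined across ancestries with Fisher's method and adjusted
by Benjamini–Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import MatchingError, UndefinedFrequencyError
from .simulate import PaintedCohort

__all__ = [
    "ancestral_allele_frequency",
    "ars_score",
    "ARSBootstrap",
    "bootstrap_individuals",
    "frequency_match_sets",
    "build_null_ars",
    "empirical_test",
    "fisher_combine",
    "bh_adjust",
    "ld_prune",
    "AncestralRiskScore",
]


def ancestral_allele_frequency(
    painting: np.ndarray, genotypes: np.ndarray
) -> np.ndarray:
    """Painting-weighted risk-allele frequencies.

    Accepts a single SNP (painting (H, K), genotypes (H,)) or a block
    (painting (H, M, K), genotypes (H, M)); returns (K,) or (M, K).
    Raises :class:`UndefinedFrequencyError` when an ancestry has zero
    total painting weight.
    """
    painting = np.asarray(painting, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    single = painting.ndim == 2
    if single:
        painting = painting[:, None, :]
        genotypes = genotypes[:, None]
    denom = painting.sum(axis=0)  # (M, K)
    bad = np.where(~(denom > 0))
    if bad[0].size:
        j, k = int(bad[0][0]), int(bad[1][0])
        raise UndefinedFrequencyError(
            f"ancestry index {k} has zero total painting weight at SNP index {j}; "
            "its allele frequency is undefined"
        )
    numer = np.einsum("hmk,hm->mk", painting, genotypes)
    freq = numer / denom
    return freq[0] if single else freq


def ars_score(freqs: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """ARS_k = sum_j f_jk beta_j for every ancestry k."""
    freqs = np.asarray(freqs, dtype=float)
    effects = np.asarray(effects, dtype=float)
    if freqs.shape[0] != effects.shape[0]:
        raise ValueError("frequency matrix and effect vector disagree on M")
    return effects @ freqs


@dataclass
class ARSBootstrap:
    """Individual-bootstrap summary of ARS uncertainty.

    ``ci_low``/``ci_high`` substitute the per-SNP frequency quantiles into
    the score (the defining construction; order can invert when some
    effects are negative).  ``ars_replicates`` holds the per-resample
    scores, from which ``sigma`` is the standard deviation and percentile
    intervals can be formed as an alternative.
    """

    freq_lower: np.ndarray
    freq_upper: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sigma: np.ndarray
    ars_replicates: np.ndarray


def bootstrap_individuals(
    painting: np.ndarray,
    genotypes: np.ndarray,
    effects: np.ndarray,
    n_boot: int = 1_000,
    rng: np.random.Generator | None = None,
    alpha: float = 0.05,
) -> ARSBootstrap:
    """Bootstrap over individuals (haplotype pairs resampled together).

    ``painting`` is (2N, M, K) haplotype-major with rows 2i, 2i+1 forming
    individual i.  Each resample recomputes every ``f_jk`` and the scores;
    frequency quantile bands are taken at ``alpha/2`` and ``1 - alpha/2``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if rng is None:
        rng = np.random.default_rng()
    painting = np.asarray(painting, dtype=float)
    genotypes = np.asarray(genotypes, dtype=float)
    n_hap, m, k = painting.shape
    if n_hap % 2:
        raise ValueError("haplotype count must be even (two per individual)")
    n_ind = n_hap // 2
    if n_ind < 2:
        raise ValueError("at least two individuals are required")

    numer = (painting * genotypes[:, :, None]).reshape(n_ind, 2, m * k).sum(axis=1)
    denom = painting.reshape(n_ind, 2, m * k).sum(axis=1)
    counts = rng.multinomial(n_ind, np.full(n_ind, 1.0 / n_ind), size=n_boot)
    counts = counts.astype(float)
    freq_b = (counts @ numer) / (counts @ denom)
    freq_b = freq_b.reshape(n_boot, m, k)

    q = np.quantile(freq_b, [alpha / 2, 1 - alpha / 2], axis=0)
    freq_lower, freq_upper = q[0], q[1]
    ars_b = np.einsum("bmk,m->bk", freq_b, np.asarray(effects, dtype=float))
    return ARSBootstrap(
        freq_lower=freq_lower,
        freq_upper=freq_upper,
        ci_low=ars_score(freq_lower, effects),
        ci_high=ars_score(freq_upper, effects),
        sigma=ars_b.std(axis=0, ddof=1),
        ars_replicates=ars_b,
    )


def frequency_match_sets(
    trait_frequency: np.ndarray,
    pool_frequency: np.ndarray,
    decimals: int = 2,
) -> list[np.ndarray]:
    """Pool indices matching each trait SNP's genome-wide frequency.

    Frequencies are rounded half-even to ``decimals`` places (1% bins by
    default) and matched by equality.  Raises :class:`MatchingError` for a
    trait SNP whose bin is empty in the pool.
    """
    trait_bins = np.round(np.asarray(trait_frequency, dtype=float), decimals)
    pool_bins = np.round(np.asarray(pool_frequency, dtype=float), decimals)
    matches = []
    for j, b in enumerate(trait_bins):
        idx = np.where(pool_bins == b)[0]
        if idx.size == 0:
            raise MatchingError(
                f"trait SNP index {j} (frequency bin {b:.{decimals}f}) has no "
                "frequency-matched SNP in the null pool"
            )
        matches.append(idx)
    return matches


def build_null_ars(
    trait_frequency: np.ndarray,
    effects: np.ndarray,
    pool_ancestry_freq: np.ndarray,
    pool_frequency: np.ndarray,
    n_draws: int = 50_000,
    rng: np.random.Generator | None = None,
    decimals: int = 2,
    keep: np.ndarray | None = None,
) -> np.ndarray:
    """Pseudo-score null draws by frequency-matched SNP resampling.

    Each draw replaces every trait SNP with a uniformly chosen matched
    pool SNP (with replacement) and applies the real effect sizes:
    ``ARS*_k = sum_j f*_jk beta_j``.  ``keep`` is an optional pruning hook:
    a precomputed index list restricting the pool (e.g. after LD pruning).
    Returns an (n_draws, K) array.
    """
    if rng is None:
        rng = np.random.default_rng()
    pool_ancestry_freq = np.asarray(pool_ancestry_freq, dtype=float)
    pool_frequency = np.asarray(pool_frequency, dtype=float)
    if keep is not None:
        pool_ancestry_freq = pool_ancestry_freq[keep]
        pool_frequency = pool_frequency[keep]
    effects = np.asarray(effects, dtype=float)
    matches = frequency_match_sets(trait_frequency, pool_frequency, decimals)
    k = pool_ancestry_freq.shape[1]
    draws = np.zeros((n_draws, k))
    for j, idx in enumerate(matches):
        pick = idx[rng.integers(0, idx.size, size=n_draws)]
        draws += effects[j] * pool_ancestry_freq[pick]
    return draws


def empirical_test(
    observed: np.ndarray,
    null_draws: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Two-sided empirical p-values against noise-inflated null draws.

    Each pseudo-score draw is inflated with Gaussian noise of SD
    ``sigma_k`` (the individual-bootstrap standard error), and
    ``p_k = 2 * min(prop(draws >= obs), prop(draws <= obs))`` capped at 1.
    A value of 0 means the observation is beyond every draw, i.e. below
    the empirical resolution ``2 / n_draws``.
    """
    if rng is None:
        rng = np.random.default_rng()
    null_draws = np.asarray(null_draws, dtype=float)
    if null_draws.ndim == 1:
        null_draws = null_draws[:, None]
    if null_draws.shape[0] == 0:
        raise ValueError("null_draws is empty")
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), observed.shape)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    noisy = null_draws + rng.normal(0.0, 1.0, size=null_draws.shape) * sigma[None, :]
    upper = (noisy >= observed[None, :]).mean(axis=0)
    lower = (noisy <= observed[None, :]).mean(axis=0)
    return np.minimum(2.0 * np.minimum(upper, lower), 1.0)


def fisher_combine(pvals: np.ndarray, min_p: float | None = None) -> float:
    """Fisher's method: chi2 = -2 sum(log p_k) against 2K degrees of freedom.

    Zero p-values (observations beyond the empirical null resolution) are
    clipped to ``min_p`` with a warning so the statistic stays finite;
    pass ``min_p = 2 / n_draws`` when the inputs are empirical.
    """
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if min_p is None:
            raise ValueError(
                "p-value of exactly 0 requires min_p (the empirical resolution) "
                "to keep the log finite"
            )
        warnings.warn(
            f"clipping zero p-value(s) to the empirical resolution {min_p:g}",
            stacklevel=2,
        )
        p = np.maximum(p, min_p)
    _, combined = stats.combine_pvalues(p, method="fisher")
    return float(combined)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ld_prune(genotypes: np.ndarray, r2_threshold: float = 0.5) -> np.ndarray:
    """Greedy LD pruning of SNP columns by squared correlation.

    Walks SNPs in order, keeping a SNP only if its r^2 with every kept SNP
    stays below the threshold.  Intended for synthetic data; real pipelines
    should pass an externally computed keep-list instead.
    """
    g = np.asarray(genotypes, dtype=float)
    kept: list[int] = []
    for j in range(g.shape[1]):
        col = g[:, j]
        if col.std() == 0:
            continue
        ok = True
        for i in kept:
            r = np.corrcoef(col, g[:, i])[0, 1]
            if r * r >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.asarray(kept, dtype=int)


class AncestralRiskScore(BaseEstimator):
    """Ancestral risk scores with bootstrap uncertainty and empirical testing.

    Parameters
    ----------
    n_boot_individuals:
        Individual-bootstrap resamples for frequency/score uncertainty.
    n_boot_snps:
        Frequency-matched SNP resamples forming the pseudo-score null.
    match_decimals:
        Rounding precision of the frequency matching (2 = 1% bins).
    ci_method:
        ``"frequency-quantile"`` substitutes the per-SNP frequency
        quantiles into the score (the defining construction);
        ``"percentile"`` takes quantiles of the bootstrap score replicates
        (well ordered even with negative effects).
    alpha:
        Confidence level complement for intervals and quantile bands.
    pool_keep:
        Optional precomputed keep-list (e.g. LD-pruned indices) restricting
        the null pool.
    random_state:
        Seed for the bootstrap and null-resampling streams.

    Attributes (after :meth:`fit`)
    ------------------------------
    freq_ : (M, K) ancestry-specific risk-allele frequencies.
    ars_ : (K,) scores; ci_low_, ci_high_, sigma_ : their uncertainty.
    null_draws_ : (n_boot_snps, K) pseudo-score draws.
    p_empirical_, p_bh_ : per-ancestry raw and BH-adjusted p-values.
    p_fisher_ : phenotype-level Fisher-combined p-value.
    ancestry_weights_, weighted_mean_ars_ : population-size weights (from
        genome-wide painting mass) and the weighted mean score.
    """

    def __init__(
        self,
        n_boot_individuals: int = 1_000,
        n_boot_snps: int = 50_000,
        match_decimals: int = 2,
        ci_method: str = "frequency-quantile",
        alpha: float = 0.05,
        pool_keep: np.ndarray | None = None,
        random_state: int | None = None,
    ):
        self.n_boot_individuals = n_boot_individuals
        self.n_boot_snps = n_boot_snps
        self.match_decimals = match_decimals
        self.ci_method = ci_method
        self.alpha = alpha
        self.pool_keep = pool_keep
        self.random_state = random_state

    def fit(self, X: PaintedCohort, y=None):
        """Run the full inference pipeline on a painted cohort."""
        if self.ci_method not in ("frequency-quantile", "percentile"):
            raise ValueError(
                "ci_method must be 'frequency-quantile' or 'percentile'"
            )
        cohort = X
        cohort.validate()
        rng = np.random.default_rng(self.random_state)

        self.ancestry_labels_ = list(cohort.ancestry_labels)
        self.freq_ = ancestral_allele_frequency(cohort.painting, cohort.genotypes)
        self.ars_ = ars_score(self.freq_, cohort.effects)

        boot = bootstrap_individuals(
            cohort.painting,
            cohort.genotypes,
            cohort.effects,
            n_boot=self.n_boot_individuals,
            rng=rng,
            alpha=self.alpha,
        )
        self.freq_lower_, self.freq_upper_ = boot.freq_lower, boot.freq_upper
        self.sigma_ = boot.sigma
        if self.ci_method == "percentile":
            q = np.quantile(
                boot.ars_replicates, [self.alpha / 2, 1 - self.alpha / 2], axis=0
            )
            self.ci_low_, self.ci_high_ = q[0], q[1]
        else:
            self.ci_low_, self.ci_high_ = boot.ci_low, boot.ci_high

        pool_freq_k = ancestral_allele_frequency(
            cohort.pool_painting, cohort.pool_genotypes
        )
        trait_gw = cohort.genotypes.mean(axis=0)
        self.null_draws_ = build_null_ars(
            trait_gw,
            cohort.effects,
            pool_freq_k,
            cohort.pool_frequency,
            n_draws=self.n_boot_snps,
            rng=rng,
            decimals=self.match_decimals,
            keep=self.pool_keep,
        )
        self.p_empirical_ = empirical_test(
            self.ars_, self.null_draws_, self.sigma_, rng=rng
        )
        self.p_bh_ = bh_adjust(self.p_empirical_)
        resolution = 2.0 / self.n_boot_snps
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.p_fisher_ = fisher_combine(self.p_empirical_, min_p=resolution)

        mass = cohort.pool_painting.sum(axis=(0, 1))
        self.ancestry_weights_ = mass / mass.sum()
        self.weighted_mean_ars_ = float(self.ancestry_weights_ @ self.ars_)
        return self

    def summary(self) -> pd.DataFrame:
        """Per-ancestry result table (score, CI, sigma, p-values)."""
        return pd.DataFrame({
            "ancestry": self.ancestry_labels_,
            "ars": self.ars_,
            "ci_low": self.ci_low_,
            "ci_high": self.ci_high_,
            "sigma": self.sigma_,
            "p_empirical": self.p_empirical_,
            "p_bh": self.p_bh_,
        })

    def null_quantiles(
        self, quantiles: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975)
    ) -> pd.DataFrame:
        """Quantile table of the pseudo-score null per ancestry
        (raincloud-style summary)."""
        rows = []
        for k, label in enumerate(self.ancestry_labels_):
            for q in quantiles:
                rows.append({
                    "ancestry": label,
                    "quantile": q,
                    "value": float(np.quantile(self.null_draws_[:, k], q)),
                })
        return pd.DataFrame(rows)
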