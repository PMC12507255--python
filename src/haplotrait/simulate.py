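"""Synthetic cohorts for local-ancestry-aware association analyses.

Two generators live here.

The first builds a two-way admixed diploid cohort for the Tractor
effect-size simulation: per-haplotype latent ancestry drawn at admixture
fraction ``a``, calibrated per-haplotype ancestry-call certainties (Beta
distributed with mean ``p`` and variance ``(0.05/p)**2``), ancestry-specific
risk-allele frequencies under the Balding–Nichols model, and a continuous
phenotype generated from the true ancestral dosages,
``Y = b0 + b1*T1 + b2*T2 + eps``.

The second builds a K-ancestry "painted" cohort for ancestral risk score
(ARS) inference: per-haplotype-per-SNP ancestry probability vectors (rows
summing to one), genotypes whose per-ancestry frequencies carry genuine
background differentiation (Balding–Nichols around each SNP's genome-wide
frequency), per-SNP risk-allele effect sizes, and a genome-wide pool of
trait-unassociated SNPs for frequency-matched null resampling.  The null
scenario (``delta = 0``) makes trait SNPs exchangeable with pool SNPs with
respect to ancestry; the alternative shifts selected ancestries' trait-SNP
frequencies by ``delta_k``.

All randomness flows through a :class:`numpy.random.Generator`; identical
seed and configuration give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "MAF_BINS",
    "CERTAINTY_GRID",
    "ADMIXTURE_GRID",
    "AdmixtureSimConfig",
    "LocalAncestrySet",
    "SimulatedCohort",
    "ARSSimConfig",
    "PaintedCohort",
    "certainty_variance",
    "simulate_local_ancestry",
    "balding_nichols_frequency",
    "simulate_genotypes",
    "true_dosages",
    "simulate_phenotype",
    "simulate_cohort",
    "generate_painted_cohort",
]

#: MAF bins used in the published simulation grid (applied to the
#: risk-allele frequency directly; the top bin is [0.20, 0.50]).
MAF_BINS = ((0.01, 0.05), (0.05, 0.10), (0.10, 0.20), (0.20, 0.50))

#: Mean local-ancestry certainty grid.
CERTAINTY_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95, 0.98)

#: Ancestry-1 admixture fraction grid.
ADMIXTURE_GRID = (0.1, 0.25, 0.5)


def certainty_variance(p: float) -> float:
    """Variance rule for per-haplotype certainties: Var = (0.05/p)**2."""
    return (0.05 / p) ** 2


def _certainty_beta_params(p: float) -> tuple[float, float]:
    """Moment-matched Beta(alpha, beta) with mean p, variance (0.05/p)**2.

    alpha = p*nu, beta = (1-p)*nu with nu = p(1-p)/var - 1.  Raises if the
    moment pair is infeasible (variance >= p(1-p)), which happens for p
    very close to (but not equal to) 1.
    """
    var = certainty_variance(p)
    nu = p * (1.0 - p) / var - 1.0
    if nu <= 0:
        raise ConfigurationError(
            f"certainty variance rule (0.05/p)^2 = {var:.6g} is not smaller than "
            f"p(1-p) = {p * (1 - p):.6g} for mean certainty p = {p}; "
            "no Beta distribution has these moments"
        )
    return p * nu, (1.0 - p) * nu


@dataclass(frozen=True)
class AdmixtureSimConfig:
    """Configuration of the two-way admixture simulation.

    Parameters
    ----------
    n_individuals:
        Diploid cohort size (published setting: 20,000).
    ancestry1_mean:
        Expected ancestry-1 fraction ``a`` of haplotypes, in (0, 1).
    mean_certainty:
        Mean local-ancestry call certainty ``p`` in [0.5, 1].  ``p = 1`` is
        the degenerate, perfectly-certain limit (point mass).
    fst:
        Balding–Nichols differentiation index between the two ancestries.
    maf_bin:
        Half-open frequency interval from which the ancestral risk-allele
        frequency ``f`` is drawn uniformly, and within which the
        per-ancestry frequencies are kept by rejection.
    beta_true:
        (intercept, ancestry-1 effect, ancestry-2 effect) of the generative
        phenotype model.
    noise_sd:
        Standard deviation of the phenotype noise.
    n_replicates:
        Number of simulation replicates in a grid run.
    seed:
        Master seed; all child streams derive from it deterministically.
    """

    n_individuals: int = 20_000
    ancestry1_mean: float = 0.5
    mean_certainty: float = 0.9
    fst: float = 0.2
    maf_bin: tuple[float, float] = (0.20, 0.50)
    beta_true: tuple[float, float, float] = (2.0, 5.0, 1.0)
    noise_sd: float = 15.0
    n_replicates: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be positive")
        if not 0.0 < self.ancestry1_mean < 1.0:
            raise ConfigurationError("ancestry1_mean must be in (0, 1)")
        if not 0.5 <= self.mean_certainty <= 1.0:
            raise ConfigurationError("mean_certainty must be in [0.5, 1]")
        if not 0.0 < self.fst < 1.0:
            raise ConfigurationError("fst must be in (0, 1)")
        lo, hi = self.maf_bin
        if not 0.0 < lo < hi <= 0.5:
            raise ConfigurationError(
                f"maf_bin must satisfy 0 < lower < upper <= 0.5, got {self.maf_bin}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if self.mean_certainty < 1.0:
            _certainty_beta_params(self.mean_certainty)  # feasibility check


@dataclass
class LocalAncestrySet:
    """Latent, true and probabilistic ancestry assignments for a cohort.

    Arrays are indexed ``[individual, copy]`` (copies d = 0, 1), with a
    trailing ancestry axis (ancestry 1 first) where applicable.

    Attributes
    ----------
    latent:
        (n, 2) binary; 1 where the latent (pre-noise) ancestry of the copy
        is ancestry 1.
    certainty:
        (n, 2) certainties ``p_id`` in [0, 1] of the eventual call.
    observed_prob:
        (n, 2, 2) observed local-ancestry probabilities ``p_ikd``;
        sums to 1 over the last axis.
    true_call:
        (n, 2, 2) one-hot true ancestry ``A*_ikd``.
    """

    latent: np.ndarray
    certainty: np.ndarray
    observed_prob: np.ndarray
    true_call: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.latent.shape[0]

    def validate(self) -> None:
        n = self.n_individuals
        assert self.latent.shape == (n, 2)
        assert self.certainty.shape == (n, 2)
        assert self.observed_prob.shape == (n, 2, 2)
        assert self.true_call.shape == (n, 2, 2)
        np.testing.assert_allclose(self.observed_prob.sum(axis=-1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(self.true_call.sum(axis=-1), 1)
        # probability reported for the latent ancestry equals the certainty
        lat = self.latent.astype(int)
        prob_latent = np.take_along_axis(
            self.observed_prob, (1 - lat)[..., None], axis=-1
        )[..., 0]
        np.testing.assert_allclose(prob_latent, self.certainty, atol=1e-12)


@dataclass
class SimulatedCohort:
    """One replicate of the two-way admixture simulation."""

    ancestry: LocalAncestrySet
    ancestral_freq: float
    ancestry_freqs: tuple[float, float]
    genotypes: np.ndarray  # (n, 2) binary risk-allele indicators G_id
    phenotype: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.ancestry.n_individuals


def simulate_local_ancestry(
    config: AdmixtureSimConfig, rng: np.random.Generator
) -> LocalAncestrySet:
    """Draw latent ancestries, certainties, observed probabilities and true calls.

    The latent ancestry-1 indicator is Bernoulli(a) per copy; certainties
    are Beta with mean ``p`` and variance ``(0.05/p)**2`` (point mass at 1
    when ``p = 1``); the observed ancestry-1 probability equals the
    certainty on copies whose latent ancestry is 1 and its complement
    otherwise; the true call is Bernoulli in the observed probability, so
    the stated certainties are calibrated by construction.
    """
    n = config.n_individuals
    a = config.ancestry1_mean
    p = config.mean_certainty

    latent1 = (rng.random((n, 2)) < a).astype(np.int8)
    if p == 1.0:
        certainty = np.ones((n, 2))
    else:
        alpha, beta = _certainty_beta_params(p)
        certainty = rng.beta(alpha, beta, size=(n, 2))
    prob1 = np.where(latent1 == 1, certainty, 1.0 - certainty)
    observed_prob = np.stack([prob1, 1.0 - prob1], axis=-1)
    true1 = (rng.random((n, 2)) < prob1).astype(np.int8)
    true_call = np.stack([true1, 1 - true1], axis=-1)
    return LocalAncestrySet(
        latent=latent1,
        certainty=certainty,
        observed_prob=observed_prob,
        true_call=true_call,
    )


def balding_nichols_frequency(
    f: float,
    fst: float,
    rng: np.random.Generator,
    maf_bin: tuple[float, float] | None = None,
    max_tries: int = 10_000,
) -> float:
    """One population frequency from the Balding–Nichols model.

    Draws ``f_k ~ Beta(f(1-Fst)/Fst, (1-f)(1-Fst)/Fst)``; when ``maf_bin``
    is given the draw is restricted to the bin by rejection sampling with a
    retry cap.
    """
    ratio = (1.0 - fst) / fst
    alpha, beta = f * ratio, (1.0 - f) * ratio
    if maf_bin is None:
        return float(rng.beta(alpha, beta))
    lo, hi = maf_bin
    chunk = 64
    for _ in range(0, max_tries, chunk):
        draws = rng.beta(alpha, beta, size=chunk)
        ok = draws[(draws >= lo) & (draws <= hi)]
        if ok.size:
            return float(ok[0])
    raise ConfigurationError(
        f"rejection sampling failed: no Balding–Nichols draw (f={f}, "
        f"Fst={fst}) fell inside the MAF bin [{lo}, {hi}] in {max_tries} tries"
    )


def simulate_genotypes(
    ancestry: LocalAncestrySet, config: AdmixtureSimConfig, rng: np.random.Generator
) -> SimulatedCohort:
    """Attach Balding–Nichols genotypes to a local-ancestry set.

    The ancestral frequency ``f`` is uniform on the MAF bin; the two
    population frequencies are Balding–Nichols draws restricted to the same
    bin; each copy's risk-allele indicator is Bernoulli in the frequency of
    its *true* ancestry.
    """
    lo, hi = config.maf_bin
    f = float(rng.uniform(lo, hi))
    f1 = balding_nichols_frequency(f, config.fst, rng, maf_bin=config.maf_bin)
    f2 = balding_nichols_frequency(f, config.fst, rng, maf_bin=config.maf_bin)
    is_anc1 = ancestry.true_call[:, :, 0] == 1
    copy_freq = np.where(is_anc1, f1, f2)
    genotypes = (rng.random(copy_freq.shape) < copy_freq).astype(np.int8)
    return SimulatedCohort(
        ancestry=ancestry,
        ancestral_freq=f,
        ancestry_freqs=(f1, f2),
        genotypes=genotypes,
    )


def true_dosages(cohort: SimulatedCohort) -> tuple[np.ndarray, np.ndarray]:
    """Ancestry-specific risk-allele dosages from the true calls.

    ``T_ik = G_i1 A*_ik1 + G_i2 A*_ik2`` for k = 1, 2.
    """
    g = cohort.genotypes
    a = cohort.ancestry.true_call
    t1 = (g * a[:, :, 0]).sum(axis=1).astype(float)
    t2 = (g * a[:, :, 1]).sum(axis=1).astype(float)
    return t1, t2


def simulate_phenotype(
    cohort: SimulatedCohort, config: AdmixtureSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Continuous phenotype from the generative model on true dosages.

    ``Y_i = b0 + b1*T_i1 + b2*T_i2 + eps_i`` with ``eps ~ N(0, noise_sd^2)``.
    """
    b0, b1, b2 = config.beta_true
    t1, t2 = true_dosages(cohort)
    y = b0 + b1 * t1 + b2 * t2
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
    return y


def simulate_cohort(
    config: AdmixtureSimConfig, rng: np.random.Generator | None = None
) -> SimulatedCohort:
    """Full cohort for one replicate: ancestry, genotypes and phenotype."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ancestry = simulate_local_ancestry(config, rng)
    cohort = simulate_genotypes(ancestry, config, rng)
    cohort.phenotype = simulate_phenotype(cohort, config, rng)
    return cohort


# ---------------------------------------------------------------------------
# Painted cohorts for ARS inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ARSSimConfig:
    """Configuration of the K-ancestry painted cohort for ARS inference.

    The generator emulates a biobank painted against a reference panel:
    each individual has global ancestry proportions (Dirichlet), each
    haplotype-SNP has a latent ancestry and a calibrated probability vector
    concentrated on it, and every SNP — trait and pool alike — carries
    genuine per-ancestry frequency differentiation from a Balding–Nichols
    draw around its genome-wide frequency (``background_fst``).  Under the
    null (``delta`` all zero) trait SNPs are exchangeable with
    frequency-matched pool SNPs; under the alternative the stated shift
    ``delta_k`` is added to ancestry k's frequency at trait SNPs.

    The pool stands in for a genome-wide SNP set, so it must be large
    enough that every 1% frequency bin holds many SNPs (the default pool
    of 3,000 over [0.01, 0.99] gives roughly 30 per bin); a small pool
    makes the matched null draws resample from too-narrow finite sets and
    distorts the empirical test.
    """

    n_individuals: int = 500
    n_ancestries: int = 8
    n_trait_snps: int = 30
    pool_size: int = 3_000
    delta: tuple[float, ...] | None = None
    background_fst: float = 0.1
    mean_certainty: float = 0.9
    effect_mean: float = 0.1
    effect_sd: float = 0.05
    trait_freq_range: tuple[float, float] = (0.05, 0.95)
    pool_freq_range: tuple[float, float] = (0.01, 0.99)
    match_decimals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestries < 2:
            raise ConfigurationError(
                f"n_ancestries must be at least 2, got {self.n_ancestries}"
            )
        if self.n_individuals <= 1 or self.n_trait_snps < 1 or self.pool_size < 1:
            raise ConfigurationError("cohort, trait-SNP and pool sizes must be positive")
        if self.delta is not None and len(self.delta) != self.n_ancestries:
            raise ConfigurationError(
                "delta must have one entry per ancestry"
            )
        if not 0.0 < self.background_fst < 1.0:
            raise ConfigurationError("background_fst must be in (0, 1)")
        if not 0.5 <= self.mean_certainty <= 1.0:
            raise ConfigurationError("mean_certainty must be in [0.5, 1]")

    @property
    def is_null(self) -> bool:
        return self.delta is None or all(d == 0 for d in self.delta)


@dataclass
class PaintedCohort:
    """K-ancestry painting probabilities, genotypes and effect sizes.

    Haplotype-major layout: row ``2*i`` and ``2*i + 1`` are the two
    haplotypes of individual ``i``.  ``painting`` is (2N, M, K) with rows
    summing to 1 over ancestries; ``genotypes`` is (2N, M) binary;
    ``effects`` holds the per-SNP risk-allele effect sizes.  The pool
    arrays describe a genome-wide set of trait-unassociated SNPs used for
    frequency-matched null resampling, with ``pool_frequency`` their
    empirical genome-wide risk-allele frequencies.
    """

    n_individuals: int
    ancestry_labels: list[str]
    painting: np.ndarray
    genotypes: np.ndarray
    effects: np.ndarray
    pool_painting: np.ndarray
    pool_genotypes: np.ndarray
    pool_frequency: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pool_frequency is None:
            self.pool_frequency = self.pool_genotypes.mean(axis=0)
        self.validate()

    @property
    def n_ancestries(self) -> int:
        return self.painting.shape[-1]

    @property
    def n_trait_snps(self) -> int:
        return self.painting.shape[1]

    def validate(self) -> None:
        h = 2 * self.n_individuals
        if self.painting.shape[0] != h or self.pool_painting.shape[0] != h:
            raise ConfigurationError("painting rows must equal 2 * n_individuals")
        for name, mat in (("painting", self.painting), ("pool_painting", self.pool_painting)):
            sums = mat.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ConfigurationError(f"{name} rows must sum to 1 within 1e-8")
        if not np.all(np.isfinite(self.effects)):
            raise ConfigurationError("effect sizes must be finite")
        if len(self.ancestry_labels) != self.n_ancestries:
            raise ConfigurationError("one label per ancestry required")


def _paint_block(
    q: np.ndarray,
    freq_gw: np.ndarray,
    fst: float,
    p_certainty: float,
    delta: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Painting probabilities, genotypes and true per-ancestry frequencies
    for one block of SNPs.

    ``q`` is (H, K) per-haplotype global ancestry proportions; ``freq_gw``
    the (S,) genome-wide frequencies.  Returns painting (H, S, K),
    genotypes (H, S) and the true frequency table (S, K).
    """
    n_hap, k = q.shape
    s = freq_gw.shape[0]
    # latent ancestry of each haplotype at each SNP
    cum = np.cumsum(q, axis=1)
    u = rng.random((n_hap, s))
    z = (u[:, :, None] > cum[:, None, :]).sum(axis=2)
    # calibrated probability vectors concentrated on the latent ancestry
    if p_certainty == 1.0:
        conf = np.ones((n_hap, s))
    else:
        alpha, beta = _certainty_beta_params(p_certainty)
        conf = rng.beta(alpha, beta, size=(n_hap, s))
    painting = np.broadcast_to(((1.0 - conf) / (k - 1))[:, :, None], (n_hap, s, k)).copy()
    np.put_along_axis(painting, z[:, :, None], conf[:, :, None], axis=2)
    # per-ancestry true frequencies: Balding–Nichols around the genome-wide f
    ratio = (1.0 - fst) / fst
    fk = rng.beta(freq_gw[:, None] * ratio, (1.0 - freq_gw[:, None]) * ratio, size=(s, k))
    if delta is not None:
        fk = fk + delta[None, :]
    fk = np.clip(fk, 1e-3, 1.0 - 1e-3)
    hap_freq = np.take_along_axis(fk[None, :, :], z[:, :, None], axis=2)[:, :, 0]
    genotypes = (rng.random((n_hap, s)) < hap_freq).astype(np.int8)
    return painting, genotypes, fk


def generate_painted_cohort(
    config: ARSSimConfig, rng: np.random.Generator | None = None
) -> PaintedCohort:
    """Generate a painted cohort with a frequency-matched null pool.

    The pool is generated first; each trait SNP is then redrawn until its
    empirical genome-wide frequency falls in a 1%-rounded bin occupied by
    at least one pool SNP, so frequency matching is guaranteed by
    construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.n_ancestries
    n_hap = 2 * config.n_individuals
    delta = None if config.is_null else np.asarray(config.delta, dtype=float)

    q_ind = rng.dirichlet(np.ones(k), size=config.n_individuals)
    q = np.repeat(q_ind, 2, axis=0)

    lo, hi = config.pool_freq_range
    pool_f = rng.uniform(lo, hi, size=config.pool_size)
    pool_painting, pool_genotypes, _ = _paint_block(
        q, pool_f, config.background_fst, config.mean_certainty, None, rng
    )
    pool_freq = pool_genotypes.mean(axis=0)
    pool_bins = set(np.round(pool_freq, config.match_decimals).tolist())

    lo, hi = config.trait_freq_range
    paint_cols, geno_cols = [], []
    for _ in range(config.n_trait_snps):
        for _attempt in range(1_000):
            f_j = rng.uniform(lo, hi, size=1)
            pj, gj, _ = _paint_block(
                q, f_j, config.background_fst, config.mean_certainty, delta, rng
            )
            emp = round(float(gj.mean()), config.match_decimals)
            if emp in pool_bins:
                break
        else:
            raise ConfigurationError(
                "could not generate a trait SNP whose empirical frequency "
                "matches any pool SNP bin"
            )
        paint_cols.append(pj[:, 0, :])
        geno_cols.append(gj[:, 0])
    painting = np.stack(paint_cols, axis=1)
    genotypes = np.stack(geno_cols, axis=1)
    effects = rng.normal(config.effect_mean, config.effect_sd, size=config.n_trait_snps)

    labels = [f"ancestry{i + 1}" for i in range(k)]
    return PaintedCohort(
        n_individuals=config.n_individuals,
        ancestry_labels=labels,
        painting=painting,
        genotypes=genotypes,
        effects=effects,
        pool_painting=pool_painting,
        pool_genotypes=pool_genotypes,
        pool_frequency=pool_freq,
    )
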