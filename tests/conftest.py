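import numpy as np
import pytest

from haplotrait import (
    AdmixtureSimConfig,
    ARSSimConfig,
    LocalAncestrySet,
    SimulatedCohort,
    generate_painted_cohort,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A simulated two-way cohort shared by read-only tests."""
    return simulate_cohort(AdmixtureSimConfig(n_individuals=600, seed=7))


@pytest.fixture(scope="session")
def painted_cohort():
    """A small null painted cohort shared by read-only ARS tests."""
    return generate_painted_cohort(
        ARSSimConfig(
            n_individuals=120, n_ancestries=3, n_trait_snps=8,
            pool_size=1500, seed=11,
        )
    )


@pytest.fixture
def make_cohort():
    """Factory for hand-built cohorts with explicit calls and probabilities.

    ``true_anc1`` and ``prob1`` are (n, 2) arrays: the true ancestry-1
    indicator and the observed ancestry-1 probability per copy.
    """

    def _make(genotypes, true_anc1, prob1, freqs=(0.3, 0.3), f=0.3):
        g = np.asarray(genotypes, dtype=np.int8)
        t1 = np.asarray(true_anc1, dtype=np.int8)
        p1 = np.asarray(prob1, dtype=float)
        ancestry = LocalAncestrySet(
            latent=t1,
            certainty=np.where(t1 == 1, p1, 1.0 - p1),
            observed_prob=np.stack([p1, 1.0 - p1], axis=-1),
            true_call=np.stack([t1, 1 - t1], axis=-1),
        )
        return SimulatedCohort(
            ancestry=ancestry, ancestral_freq=f, ancestry_freqs=tuple(freqs),
            genotypes=g,
        )

    return _make
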