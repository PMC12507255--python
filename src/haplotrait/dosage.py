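"""Tractor regressors from the four local-ancestry representations.

Given a simulated cohort, this module builds the (T1, T2, X1) design
columns of the Tractor regression under one of four ways of turning
local-ancestry information into per-copy ancestry weights ``A_ikd``:

- ``TRUTH``: the true one-hot calls;
- ``RAW``: the observed local-ancestry probabilities used as weights;
- ``BESTGUESS``: thresholded calls, ancestry 1 iff its probability >= 0.5
  (ties resolve to ancestry 1, matching the defining inequality);
- ``SAMPLING``: one Bernoulli draw per copy from the observed probability.

For every scheme ``T_ik = sum_d G_id A_ikd`` and ``X_i1 = sum_d A_i1d``, so
``t1 + t2`` always equals the individual's total risk-allele count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimulatedCohort

__all__ = ["SCHEMES", "DosageSet", "ancestry_weights", "build_dosages"]

SCHEMES = ("TRUTH", "RAW", "BESTGUESS", "SAMPLING")


@dataclass
class DosageSet:
    """Ancestry-specific dosage columns for one representation scheme."""

    scheme: str
    t1: np.ndarray
    t2: np.ndarray
    x1: np.ndarray

    def design(self) -> np.ndarray:
        """(n, 3) design block in (t1, t2, x1) column order."""
        return np.column_stack([self.t1, self.t2, self.x1])


def ancestry_weights(
    cohort: SimulatedCohort, scheme: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Per-copy ancestry weight matrix ``A_ikd`` of shape (n, 2 copies, 2 ancestries)."""
    if scheme == "TRUTH":
        return cohort.ancestry.true_call.astype(float)
    if scheme == "RAW":
        return cohort.ancestry.observed_prob.astype(float)
    if scheme == "BESTGUESS":
        call1 = (cohort.ancestry.observed_prob[:, :, 0] >= 0.5).astype(float)
        return np.stack([call1, 1.0 - call1], axis=-1)
    if scheme == "SAMPLING":
        if rng is None:
            raise ValueError("scheme 'SAMPLING' requires a random generator")
        prob1 = cohort.ancestry.observed_prob[:, :, 0]
        draw1 = (rng.random(prob1.shape) < prob1).astype(float)
        return np.stack([draw1, 1.0 - draw1], axis=-1)
    raise ValueError(f"unknown scheme {scheme!r}; valid schemes are {SCHEMES}")


def build_dosages(
    cohort: SimulatedCohort, scheme: str, rng: np.random.Generator | None = None
) -> DosageSet:
    """Construct the (T1, T2, X1) regressors under the given scheme."""
    weights = ancestry_weights(cohort, scheme, rng)
    g = cohort.genotypes.astype(float)
    t1 = (g * weights[:, :, 0]).sum(axis=1)
    t2 = (g * weights[:, :, 1]).sum(axis=1)
    x1 = weights[:, :, 0].sum(axis=1)
    return DosageSet(scheme=scheme, t1=t1, t2=t2, x1=x1)
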