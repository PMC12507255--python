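"""Tractor regression and the replicate simulation grid.

The Tractor model for a continuous outcome at a single SNP in a two-way
admixed cohort is

    Y = b0 + b1*T1 + b2*T2 + b3*X1 + sum_j b_{j+3} C_j + eps,

where T_k is the ancestry-k risk-allele dosage, X1 the ancestry-1 locus
count and C_j optional covariates.  :class:`TractorRegressor` fits it by
ordinary least squares with classical standard errors; :func:`run_grid`
repeats the whole generative pipeline over a grid of admixture fractions,
MAF bins and certainty levels, fitting each replicate under one or more
local-ancestry representations and summarizing mean coefficient estimates
and standard errors per cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .dosage import SCHEMES, DosageSet, build_dosages
from .exceptions import SingularDesignError
from .simulate import AdmixtureSimConfig, simulate_cohort

__all__ = ["TractorRegressor", "TractorFit", "fit_tractor", "run_grid"]

#: Fixed column order of the grid summary table.
GRID_COLUMNS = [
    "scheme", "a", "maf_low", "maf_high", "p",
    "mean_beta1", "mean_beta2", "mc_se_beta1", "mc_se_beta2",
    "mean_se_beta1", "mean_se_beta2", "n_replicates", "n_used", "n_excluded",
]


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    """Raise :class:`SingularDesignError` naming a collinear column."""
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = design.shape[0] * np.finfo(float).eps * max(diag.max(), 1.0)
    bad = np.where(diag < tol)[0]
    if bad.size:
        raise SingularDesignError(
            f"design matrix is rank deficient; column(s) "
            f"{[names[i] for i in bad]} are collinear with earlier columns"
        )


class TractorRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares with classical standard errors.

    Fits ``y ~ 1 + X`` (or ``y ~ X`` when ``fit_intercept=False``) via a
    numerically stable decomposition, exposing both scikit-learn style
    ``coef_``/``intercept_`` and the full coefficient/standard-error
    vectors needed to summarize effect-size recovery.

    Attributes
    ----------
    params_ : ndarray
        Coefficients in design order (intercept first when fitted).
    bse_ : ndarray
        Classical standard errors ``sqrt(diag(sigma2 * (D'D)^-1))``.
    coef_, intercept_, se_, intercept_se_ :
        The same quantities split scikit-learn style.
    """

    def __init__(self, fit_intercept: bool = True):
        self.fit_intercept = fit_intercept

    def fit(self, X, y, column_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        names = list(column_names) if column_names else [
            f"x{i + 1}" for i in range(X.shape[1])
        ]
        if self.fit_intercept:
            design = np.column_stack([np.ones(X.shape[0]), X])
            names = ["intercept"] + names
        else:
            design = X
        _check_full_rank(design, names)
        res = sm.OLS(y, design).fit()
        self.params_ = res.params
        self.bse_ = res.bse
        self.column_names_ = names
        self.n_used_ = int(X.shape[0])
        self.n_features_in_ = X.shape[1]
        if self.fit_intercept:
            self.intercept_ = float(res.params[0])
            self.coef_ = res.params[1:]
            self.intercept_se_ = float(res.bse[0])
            self.se_ = res.bse[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = res.params
            self.intercept_se_ = 0.0
            self.se_ = res.bse
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_


@dataclass
class TractorFit:
    """Coefficients and standard errors of one Tractor fit.

    ``beta_hat`` is ordered (b0, b1, b2, b3, covariates...).
    """

    beta_hat: np.ndarray
    se_hat: np.ndarray
    n_used: int
    scheme: str

    @property
    def beta1(self) -> float:
        return float(self.beta_hat[1])

    @property
    def beta2(self) -> float:
        return float(self.beta_hat[2])


def fit_tractor(
    y: np.ndarray, dosages: DosageSet, covariates: np.ndarray | None = None
) -> TractorFit:
    """Fit the Tractor regression of y on (T1, T2, X1) plus covariates."""
    design = dosages.design()
    names = ["t1", "t2", "x1"]
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        design = np.column_stack([design, covariates])
        names += [f"c{i + 1}" for i in range(covariates.shape[1])]
    model = TractorRegressor().fit(design, y, column_names=names)
    return TractorFit(
        beta_hat=model.params_,
        se_hat=model.bse_,
        n_used=model.n_used_,
        scheme=dosages.scheme,
    )


def _replicate_rng(seed: int, cell_index: int, rep: int) -> np.random.Generator:
    """Deterministic child stream for one replicate of one grid cell."""
    return np.random.default_rng(np.random.SeedSequence((seed, cell_index, rep)))


def run_grid(
    config: AdmixtureSimConfig,
    schemes: tuple[str, ...] | list[str] = SCHEMES,
    a_values: list[float] | None = None,
    p_values: list[float] | None = None,
    maf_bins: list[tuple[float, float]] | None = None,
    n_replicates: int | None = None,
    return_replicates: bool = False,
):
    """Run the replicate grid and summarize effect-size recovery per cell.

    Every replicate redraws the whole cohort (ancestry, certainties,
    frequencies, genotypes and noise) from its own child stream; the same
    cohort is reused across schemes within a replicate so scheme
    comparisons are paired.  Replicates whose design is singular for a
    scheme are excluded from that scheme's summary and counted.

    Returns the summary :class:`~pandas.DataFrame` (one row per
    scheme x a x maf_bin x p cell), or a ``(summary, replicates)`` pair
    when ``return_replicates`` is true.
    """
    for s in schemes:
        if s not in SCHEMES:
            raise ValueError(f"unknown scheme {s!r}; valid schemes are {SCHEMES}")
    a_values = a_values if a_values is not None else [config.ancestry1_mean]
    p_values = p_values if p_values is not None else [config.mean_certainty]
    maf_bins = maf_bins if maf_bins is not None else [config.maf_bin]
    n_reps = n_replicates if n_replicates is not None else config.n_replicates

    summary_rows = []
    replicate_rows: list[dict] = []
    cells = list(itertools.product(a_values, maf_bins, p_values))
    for cell_index, (a, maf_bin, p) in enumerate(cells):
        cell_cfg = replace(
            config, ancestry1_mean=a, maf_bin=tuple(maf_bin), mean_certainty=p
        )
        results: dict[str, list[tuple[float, float, float, float]]] = {
            s: [] for s in schemes
        }
        excluded = {s: 0 for s in schemes}
        for rep in range(n_reps):
            rng = _replicate_rng(config.seed, cell_index, rep)
            cohort = simulate_cohort(cell_cfg, rng)
            for scheme in schemes:
                try:
                    fit = fit_tractor(
                        cohort.phenotype, build_dosages(cohort, scheme, rng)
                    )
                except SingularDesignError:
                    excluded[scheme] += 1
                    continue
                results[scheme].append(
                    (fit.beta1, fit.beta2, float(fit.se_hat[1]), float(fit.se_hat[2]))
                )
                if return_replicates:
                    replicate_rows.append({
                        "scheme": scheme, "a": a, "maf_low": maf_bin[0],
                        "maf_high": maf_bin[1], "p": p, "replicate": rep,
                        "beta1": fit.beta1, "beta2": fit.beta2,
                        "se_beta1": float(fit.se_hat[1]),
                        "se_beta2": float(fit.se_hat[2]),
                    })
        for scheme in schemes:
            arr = np.asarray(results[scheme])
            n_used = arr.shape[0]
            if n_used == 0:
                means = [np.nan] * 4
                mc = [np.nan, np.nan]
            else:
                means = arr.mean(axis=0).tolist()
                mc = (arr[:, :2].std(axis=0, ddof=1) / np.sqrt(n_used)).tolist()
            summary_rows.append({
                "scheme": scheme, "a": a, "maf_low": maf_bin[0],
                "maf_high": maf_bin[1], "p": p,
                "mean_beta1": means[0], "mean_beta2": means[1],
                "mc_se_beta1": mc[0], "mc_se_beta2": mc[1],
                "mean_se_beta1": means[2], "mean_se_beta2": means[3],
                "n_replicates": n_reps, "n_used": n_used,
                "n_excluded": excluded[scheme],
            })
    summary = pd.DataFrame(summary_rows, columns=GRID_COLUMNS)
    if return_replicates:
        return summary, pd.DataFrame(replicate_rows)
    return summary
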