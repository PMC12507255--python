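"""SNP loadings of component matrices and their genomic localization.

A component matrix (haplotype components learned from painting patterns,
or principal components of the genotype matrix) can be projected onto the
genotypes to obtain per-SNP loadings.  Components that track genome-wide
population structure spread their absolute loadings thinly along the
genome, while components that tag a localized LD block concentrate them;
the lag-1 autocorrelation of absolute loadings along genome order
separates the two regimes, and binned absolute-loading profiles show where
the weight sits.

For an N x C component matrix H and column-centered genotypes X, the
projected loadings are the least-squares solution
``V_h = ((H'H)^-1 H'X)'``; for principal components the loadings are the
top right-singular vectors of X.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import SingularDesignError

__all__ = [
    "LoadingsMatrix",
    "component_loadings",
    "localization_profile",
    "ComponentLoadings",
]


@dataclass
class LoadingsMatrix:
    """L SNPs x C components loading matrix with its provenance tag."""

    loadings: np.ndarray
    component_kind: str  # "HC-projected" or "PC-SVD"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.loadings)):
            raise ValueError("loadings contain non-finite entries")
        if self.loadings.shape[0] < 2:
            raise ValueError("at least two SNPs are required")

    @property
    def n_snps(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def component_loadings(
    genotypes: np.ndarray,
    components: np.ndarray | None = None,
    mode: str = "hc",
    n_components: int | None = None,
    center: bool = True,
) -> LoadingsMatrix:
    """SNP loadings by least-squares projection (``mode="hc"``) or SVD
    (``mode="pc"``).

    Genotype columns are centered before either computation so the two
    loading sets are comparable.  HC mode requires a full-column-rank
    component matrix and returns the least-squares projection; PC mode
    returns the top right-singular vectors.
    """
    x = np.asarray(genotypes, dtype=float)
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if mode == "hc":
        if components is None:
            raise ValueError("mode 'hc' requires a component matrix")
        h = np.asarray(components, dtype=float)
        if h.shape[0] != x.shape[0]:
            raise ValueError("components and genotypes disagree on sample count")
        if np.linalg.matrix_rank(h) < h.shape[1]:
            raise SingularDesignError(
                "component matrix is rank deficient; the projection "
                "(H'H)^-1 H'X is undefined"
            )
        coeff, *_ = np.linalg.lstsq(h, x, rcond=None)
        return LoadingsMatrix(loadings=coeff.T, component_kind="HC-projected")
    if mode == "pc":
        c = n_components if n_components is not None else min(x.shape)
        _, _, vt = np.linalg.svd(x, full_matrices=False)
        return LoadingsMatrix(loadings=vt[:c].T, component_kind="PC-SVD")
    raise ValueError(f"unknown mode {mode!r}; use 'hc' or 'pc'")


def _lag1_acf(series: np.ndarray) -> float:
    """Standard biased (divide-by-n) autocorrelation at lag 1."""
    if np.ptp(series) == 0 or np.allclose(series, series[0]):
        raise ValueError("|loadings| series has zero variance; ACF is undefined")
    centered = series - series.mean()
    denom = float(centered @ centered)
    return float(centered[:-1] @ centered[1:]) / denom


def localization_profile(
    loadings: LoadingsMatrix | np.ndarray, bin_size: int = 100
) -> tuple[np.ndarray, pd.DataFrame]:
    """Lag-1 ACF of absolute loadings plus binned genome profiles.

    Each component's absolute loadings are scaled to unit Euclidean norm
    (so differently scaled loading sets are comparable) before the ACF;
    the profile sums the scaled absolute loadings over consecutive bins of
    ``bin_size`` SNPs in genome order (a final partial bin is kept).

    Returns ``(acf1, profile)`` where ``acf1`` is a (C,) array and
    ``profile`` a long table with columns component, bin_index, value.
    """
    mat = loadings.loadings if isinstance(loadings, LoadingsMatrix) else np.asarray(loadings)
    if mat.ndim == 1:
        mat = mat[:, None]
    n_snps, n_comp = mat.shape
    if n_snps <= bin_size:
        raise ValueError("need more SNPs than the bin size")
    acf = np.empty(n_comp)
    rows = []
    for c in range(n_comp):
        w = np.abs(mat[:, c])
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(
                f"component {c} has all-zero loadings; ACF is undefined"
            )
        w = w / norm
        acf[c] = _lag1_acf(w)
        n_bins = int(np.ceil(n_snps / bin_size))
        for b in range(n_bins):
            rows.append({
                "component": c,
                "bin_index": b,
                "value": float(w[b * bin_size:(b + 1) * bin_size].sum()),
            })
    return acf, pd.DataFrame(rows)


class ComponentLoadings(BaseEstimator):
    """Estimator wrapper around the loading projection and its diagnostics.

    Parameters
    ----------
    mode: "hc" (least-squares projection of a supplied component matrix)
        or "pc" (right-singular vectors of the genotype matrix).
    n_components: number of components kept in PC mode.
    center: column-center genotypes before projection/decomposition.
    bin_size: SNPs per bin of the localization profile.
    """

    def __init__(
        self,
        mode: str = "hc",
        n_components: int | None = None,
        center: bool = True,
        bin_size: int = 100,
    ):
        self.mode = mode
        self.n_components = n_components
        self.center = center
        self.bin_size = bin_size

    def fit(self, X, H=None):
        result = component_loadings(
            X, components=H, mode=self.mode,
            n_components=self.n_components, center=self.center,
        )
        self.loadings_ = result.loadings
        self.component_kind_ = result.component_kind
        return self

    def localization(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Lag-1 ACF and binned profile of the fitted loadings."""
        return localization_profile(
            LoadingsMatrix(self.loadings_, self.component_kind_),
            bin_size=self.bin_size,
        )
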