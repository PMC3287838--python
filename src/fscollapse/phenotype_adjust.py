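"""Covariate selection, ancestry principal components and phenotype adjustment.

Quantitative traits are adjusted before any gene-level testing: the residuals
of an ordinary least-squares regression of the trait on the selected
confounders (plus the top ancestry PCs) become the "adjusted phenotype" that
every downstream statistic sees.  Adjusting upstream keeps the per-gene
regressions simple (one predictor, 1 df) and keeps the permutation null
exchangeable.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import GenotypeMatrix

__all__ = [
    "PhenotypeVector",
    "select_covariates",
    "compute_pcs",
    "adjust_phenotype",
]


@dataclasses.dataclass
class PhenotypeVector:
    """A quantitative trait with sample ids and an adjusted flag."""

    samples: list[str]
    values: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.samples) != self.values.size:
            raise ValueError("values must be 1-d and match the sample list")
        if not np.isfinite(self.values).all():
            raise ValueError("phenotype values must be finite")


def select_covariates(
    y: np.ndarray | PhenotypeVector,
    candidates: pd.DataFrame,
    alpha_cov: float = 0.05,
    invert: bool = False,
) -> list[str]:
    """Screen candidate confounders with one multivariate OLS fit.

    Fits y on all candidates jointly (with intercept) and returns the names
    whose coefficient p-value is below ``alpha_cov``.  ``invert=True`` selects
    p-values *above* the threshold instead — a deliberately non-standard rule
    kept behind a flag for strict reproduction of published pipelines that
    state it; confounder adjustment normally wants the associated covariates.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    if candidates.shape[1] == 0:
        return []
    X = sm.add_constant(candidates.astype(float), has_constant="add")
    model = sm.OLS(yv, X)
    res = model.fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("candidate covariates are collinear (singular design)")
    pvals = res.pvalues.drop("const")
    if invert:
        return [name for name in candidates.columns if pvals[name] > alpha_cov]
    return [name for name in candidates.columns if pvals[name] < alpha_cov]


def compute_pcs(gm: GenotypeMatrix, k: int = 5) -> pd.DataFrame:
    """Top-k ancestry principal components of the standardized genotype matrix.

    Columns are centered by their mean and scaled by sqrt(p(1-p)) with the
    posterior allele-frequency estimate p = (1 + sum_i g_ij) / (2 + 2n) — the
    standardization customary for genotype PCA, which keeps the scale defined
    even for monomorphic columns.  The returned columns are the unit-norm top
    eigenvectors of the sample covariance of the standardized matrix, sign
    fixed so each eigenvector's largest-magnitude entry is positive.
    """
    n, p = gm.counts.shape
    if k >= n or k > p:
        raise ValueError(f"k={k} exceeds the rank bound min(n_samples-1, n_variants)")
    G = gm.counts.astype(float)
    freq = (1.0 + G.sum(axis=0)) / (2.0 + 2.0 * n)
    if (G.std(axis=0) == 0).all():
        raise ValueError("all variants monomorphic; PCA undefined")
    X = (G - G.mean(axis=0)) / np.sqrt(freq * (1.0 - freq))
    # left singular vectors of X = eigenvectors of X X^T (the sample covariance
    # up to a constant); economy SVD is cheaper than forming the covariance
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    evals = s**2
    if k > np.sum(evals > evals[0] * 1e-12):
        raise ValueError(f"k={k} exceeds the numerical rank of the genotype matrix")
    pcs = U[:, :k]
    flip = np.sign(pcs[np.abs(pcs).argmax(axis=0), np.arange(k)])
    pcs = pcs * flip
    return pd.DataFrame(
        pcs, index=pd.Index(gm.samples, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )


def adjust_phenotype(
    y: np.ndarray | PhenotypeVector, covariates: pd.DataFrame | None
) -> np.ndarray:
    """OLS residuals of y on [intercept, covariates] — the adjusted phenotype.

    With no covariates this reduces to centering.  Residuals sum to zero and
    are orthogonal to every design column.
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return yv - yv.mean()
    X = np.column_stack([np.ones(yv.size), covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    return yv - X @ beta
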