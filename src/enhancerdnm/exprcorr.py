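"""Covariate-adjusted co-expression screen against a target gene.

The screen follows a regress-then-correlate design: expression of every gene
is first residualized on the sample covariates (numeric age plus a one-hot
encoded brain region with a reference level), then each gene's residuals are
rank-correlated (Spearman, midrank ties) with the target gene's residuals.
Genes passing |rho| > threshold are clustered agglomeratively on the signed
distance 1 - rho with average linkage; cutting the dendrogram into two
groups separates the positively from the negatively correlated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "expressed_genes",
    "residualize",
    "correlate_with_target",
    "select_correlated",
    "cluster_genes",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample covariates.

    ``values``: DataFrame, genes in rows, samples in columns (log-scale or
    TPM — the scale is declared by the caller, not inferred).
    ``covariates``: DataFrame indexed by sample with numeric ``age`` and
    categorical ``region`` columns.
    """

    values: pd.DataFrame
    covariates: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self):
        missing = [s for s in self.values.columns if s not in self.covariates.index]
        if missing:
            raise ValueError(f"samples without covariates: {missing[:5]}")
        cov = self.covariates.loc[list(self.values.columns)]
        if cov[["age", "region"]].isna().any().any():
            raise ValueError("covariates contain missing values for included samples")
        self.covariates = cov


def expressed_genes(matrix: ExpressionMatrix, sample: str, cutoff: float = 2.0) -> set[str]:
    """Genes with expression strictly greater than ``cutoff`` in one sample."""
    if sample not in matrix.values.columns:
        raise KeyError(f"unknown sample/tissue {sample!r}")
    col = matrix.values[sample]
    return set(col.index[col > cutoff])


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    age = cov["age"].astype(float).to_numpy()
    dummies = pd.get_dummies(cov["region"], prefix="region", drop_first=True)
    X = np.column_stack([np.ones(len(cov)), age, dummies.to_numpy(dtype=float)])
    names = ["intercept", "age", *dummies.columns]
    return X, names


def residualize(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene OLS residuals of expression on age + brain region.

    The design must be full rank (collinear columns are named in the error);
    with an intercept in the design every gene's residuals sum to ~0.
    """
    X, names = _design_matrix(matrix.covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: drop each in turn and re-check
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need more samples than design columns to define residuals")
    Y = matrix.values.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return pd.DataFrame(resid.T, index=matrix.values.index, columns=matrix.values.columns)


def correlate_with_target(
    residuals: pd.DataFrame, target_gene: str
) -> tuple[pd.Series, list[str]]:
    """Spearman correlation of each gene's residuals with the target's.

    Returns ``(rho, excluded)`` where ``excluded`` lists genes with zero
    residual variance (their rank correlation is undefined).  Midrank ties;
    rho(target, target) = 1 by construction.
    """
    if target_gene not in residuals.index:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    target = residuals.loc[target_gene].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValueError("target gene has constant residuals")
    R = residuals.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, R)
    sd = ranks.std(axis=1)
    excluded = list(residuals.index[sd == 0])
    t_rank = rankdata(target)
    t_center = t_rank - t_rank.mean()
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (centered @ t_center) / (
            np.sqrt((centered**2).sum(axis=1)) * np.sqrt((t_center**2).sum())
        )
    out = pd.Series(rho, index=residuals.index).drop(excluded)
    return out, excluded


def select_correlated(rho: pd.Series, threshold: float = 0.6) -> set[str]:
    """Genes with |rho| strictly greater than the threshold."""
    if ((rho < -1 - 1e-9) | (rho > 1 + 1e-9)).any():
        raise ValueError("correlations must lie in [-1, 1]")
    return set(rho.index[rho.abs() > threshold])


def cluster_genes(corr: pd.DataFrame, n_clusters: int = 2):
    """Average-linkage agglomerative clustering on distance 1 - rho.

    The signed distance keeps anti-correlated genes far apart, so a 2-cut
    separates genes positively vs negatively correlated with the target.
    Deterministic given input order (scipy's lowest-index merge ordering).
    Returns ``(linkage_matrix, labels)`` with labels indexed by gene.
    """
    if corr.shape[0] != corr.shape[1] or not np.allclose(
        corr.to_numpy(), corr.to_numpy().T, atol=1e-10
    ):
        raise ValueError("correlation matrix must be symmetric")
    if corr.shape[0] == 1:
        return np.empty((0, 4)), pd.Series([1], index=corr.index)
    dist = 1.0 - corr.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=corr.index)
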