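"""Feature-correlation analysis with shuffle-null thresholds, plus PCA.

Pairwise Pearson correlations among the 32 phenotype features are
compared against a per-pair significance threshold: the 95th percentile
of |r| under surrogate tables built by permuting each feature column
across mice independently.  Because every column keeps its identity, a
feature is only ever compared against shuffled values of the same
feature type.  PCA on the z-scored table summarizes which features carry
the between-animal variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "CorrelationReport",
    "correlation_matrix",
    "shuffle_threshold",
    "significant_pairs",
    "correlation_report",
    "pca_summary",
]


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    thresholds: pd.DataFrame
    significant: pd.DataFrame
    n_shuffles: int
    seed: int


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson r matrix with unit diagonal.

    Constant columns have undefined correlations; they are kept as NaN
    with a warning.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 mice for a correlation matrix")
    const = [c for c in table.columns if table[c].nunique() <= 1]
    if const:
        warnings.warn(f"constant columns {const} excluded from correlation "
                      "(r undefined)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = table.corr(method="pearson")
    np.fill_diagonal(r.values, 1.0)
    return r


def _abs_corr(X: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(np.corrcoef(X, rowvar=False))


def shuffle_threshold(table: pd.DataFrame, n_shuffles: int = 10_000,
                      q: float = 0.95, seed: int = 0,
                      block_by_mouse: bool = False) -> pd.DataFrame:
    """Per-pair q-quantile of |r| over column-permuted surrogate tables.

    Each surrogate permutes every feature column's values across mice
    independently, preserving feature identity (and hence feature type).
    ``block_by_mouse`` instead permutes whole rows within each column
    block simultaneously — a stricter surrogate kept behind a flag.
    """
    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives an unstable quantile")
    rng = np.random.default_rng(seed)
    X = table.to_numpy(float)
    n, p = X.shape
    maxima = np.empty((n_shuffles, p, p))
    for s in range(n_shuffles):
        if block_by_mouse:
            perm = rng.permutation(n)
            Xs = X[perm]
        else:
            Xs = np.empty_like(X)
            for j in range(p):
                Xs[:, j] = X[rng.permutation(n), j]
        maxima[s] = _abs_corr(Xs)
    thr = np.quantile(maxima, q, axis=0)
    thr = (thr + thr.T) / 2.0
    return pd.DataFrame(thr, index=table.columns, columns=table.columns)


def significant_pairs(r: pd.DataFrame, thresholds: pd.DataFrame
                      ) -> pd.DataFrame:
    """|r| - threshold > 0 (strict), diagonal excluded."""
    sig = (r.abs() - thresholds) > 0
    np.fill_diagonal(sig.values, False)
    return sig


def correlation_report(table: pd.DataFrame, n_shuffles: int = 10_000,
                       q: float = 0.95, seed: int = 0) -> CorrelationReport:
    r = correlation_matrix(table)
    thr = shuffle_threshold(table, n_shuffles=n_shuffles, q=q, seed=seed)
    return CorrelationReport(r, thr, significant_pairs(r, thr),
                             n_shuffles, seed)


def pca_summary(table: pd.DataFrame, n_top: int = 5) -> dict:
    """PCA of the column-standardized feature table.

    Returns variance fractions (summing to 1), the loading matrix, and the
    strongest-loading features per component.
    """
    X = table.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    pca = PCA()
    pca.fit(Z)
    loadings = pd.DataFrame(
        pca.components_.T, index=table.columns,
        columns=[f"PC{i + 1}" for i in range(pca.n_components_)])
    top = {
        pc: list(loadings[pc].abs().sort_values(ascending=False)
                 .head(n_top).index)
        for pc in loadings.columns}
    return {
        "variance_fraction": pca.explained_variance_ratio_,
        "loadings": loadings,
        "top_features": top,
    }
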