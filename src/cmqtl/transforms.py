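"""rankZ normalization and unit-variance PCA.

Mapping traits are forced to a Gaussian shape with the rank-based inverse
normal transform (rankZ): ranks r (ties averaged) are mapped through
Phi^{-1}((r - 0.5) / n) on the non-missing entries, missing entries are
preserved. Feature structure is summarized with PCA on features centered
and scaled to unit variance (i.e. the correlation structure).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


def rank_z(values, offset: float = 0.5):
    """Rank-based inverse normal transform.

    Ranks are computed on non-missing entries with average ranks for ties,
    then mapped through the standard normal quantile of (r - offset) / n.
    Missing entries (NaN) stay missing. All-tied input maps every value to
    the single mid-rank quantile and warns.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    v = x[mask]
    if np.ptp(v) == 0.0:
        warnings.warn("all values identical; rankZ output degenerate")
    ranks = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / n)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def rank_z_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """rankZ each column of a wide phenotype table (individuals x traits)."""
    return pheno.apply(rank_z, axis=0)


class PcaResult:
    """Scores, loadings, and percent variance per component."""

    def __init__(self, scores, loadings, percent_variance, feature_names, dropped):
        self.scores = scores
        self.loadings = loadings
        self.percent_variance = percent_variance
        self.feature_names = feature_names
        self.dropped = dropped


def pca_unit_variance(
    feature_matrix,
    n_components: int = None,
    max_missing_fraction: float = 0.0,
) -> PcaResult:
    """PCA of features scaled to unit variance.

    Constant features are dropped with a warning, as are features whose
    missing fraction exceeds ``max_missing_fraction``; remaining missing
    entries are imputed at the feature mean (0 after standardization).
    Percent variance sums to 100 over the full component set.
    """
    if isinstance(feature_matrix, pd.DataFrame):
        names = list(feature_matrix.columns)
        X = feature_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(feature_matrix, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 observations")

    dropped = []
    keep = []
    for j in range(X.shape[1]):
        col = X[:, j]
        miss = np.mean(~np.isfinite(col))
        if miss > max_missing_fraction:
            dropped.append(names[j])
            continue
        finite = col[np.isfinite(col)]
        if finite.size == 0 or np.ptp(finite) == 0.0:
            dropped.append(names[j])
            continue
        keep.append(j)
    if dropped:
        warnings.warn(f"dropping {len(dropped)} constant/too-missing features")
    if not keep:
        raise ValueError("no usable features")
    X = X[:, keep]
    names = [names[j] for j in keep]

    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    Z = (X - mu) / sd
    Z[~np.isfinite(Z)] = 0.0

    n_comp_full = min(Z.shape)
    pca = PCA(n_components=n_comp_full, svd_solver="full")
    scores = pca.fit_transform(Z)
    pct = 100.0 * pca.explained_variance_ratio_
    if n_components is not None:
        scores = scores[:, :n_components]
    return PcaResult(scores, pca.components_, pct, names, dropped)
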