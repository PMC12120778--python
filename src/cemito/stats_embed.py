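"""Statistical tests and feature embeddings.

Pearson correlation for linear association; two-sided Wilcoxon rank-sum
(Mann-Whitney) for distribution comparisons, exact by enumeration for
small tie-free samples; standardized PCA for the 8 neuronal mitochondria
features and seeded UMAP for the 5 muscle features. P-values below 1e-20
display as "P ~ 0". No multiple-testing correction is applied: raw
rank-sum p-values are reported throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import TestResult

EXACT_WILCOXON_MAX_N = 20


def pearson(x, y) -> TestResult:
    """Pearson correlation with a two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(statistic=float(r), p_value=float(p),
                      n=(int(x.size),), method="pearson")


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum test.

    ``mode='auto'`` enumerates the exact null when the combined sample is
    small (n_x + n_y <= 20) and tie-free, else uses the normal
    approximation with tie and continuity corrections. The statistic
    reported is the Mann-Whitney U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if mode == "auto":
        mode = "exact" if (x.size + y.size <= EXACT_WILCOXON_MAX_N
                           and not has_ties) else "approx"
    if mode == "exact" and has_ties:
        raise ValueError("exact enumeration requires tie-free samples")
    if mode == "exact":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "approx":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=float(res.statistic), p_value=float(min(res.pvalue, 1.0)),
                      n=(int(x.size), int(y.size)), method=f"wilcoxon_rank_sum_{mode}")


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------

def _standardize(features: pd.DataFrame) -> np.ndarray:
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in feature table")
    sd = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance feature column: {features.columns[zero[0]]!r}")
    return (X - X.mean(axis=0)) / sd


@dataclass
class PCAEmbedding:
    coordinates: np.ndarray  # (n, 2)
    loadings: np.ndarray  # (2, n_features)
    explained_variance_ratio: np.ndarray  # (2,)
    feature_names: tuple[str, ...]


def pca_embed(features: pd.DataFrame) -> PCAEmbedding:
    """Standardize per column and project onto the first two principal
    components. Sign convention: each component's largest-magnitude
    loading is positive, so embeddings are reproducible across runs."""
    from sklearn.decomposition import PCA

    if len(features) < 3:
        raise ValueError("need at least 3 rows")
    X = _standardize(features)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(2):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1
            coords[:, k] *= -1
    return PCAEmbedding(coordinates=coords, loadings=loadings,
                        explained_variance_ratio=pca.explained_variance_ratio_[:2],
                        feature_names=tuple(features.columns))


def umap_embed(features: pd.DataFrame, seed: int = 0,
               n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """Seeded 2D UMAP of standardized features; deterministic given seed."""
    import umap

    if len(features) < 10:
        raise ValueError("need at least 10 rows")
    if n_neighbors >= len(features):
        raise ValueError("n_neighbors must be below the number of rows")
    X = _standardize(features)
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    return np.asarray(reducer.fit_transform(X), dtype=float)
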