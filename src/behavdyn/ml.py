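"""Machine-learning stage: variable ranking, t-SNE, K-means, PCA projection.

Variable ranking orders features by the value of a univariate scoring
function against the condition label, after equal-frequency discretization
of continuous features. Three filter scores are provided: information gain
(bits), Gini mean decrease impurity, and the chi-squared statistic of the
feature-by-label contingency table. The embedding / clustering / projection
operations wrap scikit-learn estimators with deterministic seeding and the
conventions used throughout the package (complete rows only, sign-fixed
principal components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import adjusted_rand_score

from .features import FeatureTable

__all__ = [
    "RankingResult",
    "EmbeddingResult",
    "ClusterResult",
    "ProjectionResult",
    "RANKING_METHODS",
    "discretize_equal_frequency",
    "information_gain",
    "gini_gain",
    "chi2_score",
    "rank_variables",
    "tsne_embed",
    "kmeans_cluster",
    "pca_projection",
]

RANKING_METHODS = ("info_gain", "gini", "chi2")


def discretize_equal_frequency(values, k: int = 4) -> np.ndarray:
    """Equal-frequency (quantile) discretization into at most k bins.

    Cut points are the k-1 inner quantiles; duplicate cut points are merged,
    so fewer effective bins result when the data has few distinct values.
    Deterministic: no randomness, ties resolved by the quantile definition.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty sequence")
    if k < 1:
        raise ValueError("k must be >= 1")
    cuts = np.unique(np.quantile(values, np.linspace(0, 1, k + 1)[1:-1]))
    return np.searchsorted(cuts, values, side="left")


def _entropy_of_counts(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _gini_of_counts(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def _contingency(x, y) -> pd.DataFrame:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have equal length")
    return pd.crosstab(pd.Series(x), pd.Series(y))


def information_gain(x, y) -> float:
    """Mutual information between a categorical feature and the labels:
    H(Y) - sum_v p(x=v) H(Y | x=v), in bits."""
    table = _contingency(x, y).to_numpy(dtype=float)
    n = table.sum()
    h_y = _entropy_of_counts(table.sum(axis=0))
    h_y_given_x = sum(
        row.sum() / n * _entropy_of_counts(row) for row in table if row.sum() > 0
    )
    return h_y - h_y_given_x


def gini_gain(x, y) -> float:
    """Mean decrease in Gini impurity: Gini(Y) - sum_v p(x=v) Gini(Y|x=v)."""
    table = _contingency(x, y).to_numpy(dtype=float)
    n = table.sum()
    g_y = _gini_of_counts(table.sum(axis=0))
    g_y_given_x = sum(row.sum() / n * _gini_of_counts(row) for row in table if row.sum() > 0)
    return g_y - g_y_given_x


def chi2_score(x, y) -> float:
    """Pearson chi-squared statistic sum (O - E)^2 / E of the contingency
    table, without continuity correction; zero rows/columns are dropped."""
    table = _contingency(x, y).to_numpy(dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    return float(chi2_contingency(table, correction=False).statistic)


_SCORERS = {"info_gain": information_gain, "gini": gini_gain, "chi2": chi2_score}


@dataclass(frozen=True)
class RankingResult:
    """Per-method feature scores and descending rank orders."""

    scores: pd.DataFrame  # index: feature, columns: method
    order: dict[str, list[str]]  # method -> features, best first
    n_rows: int

    def top(self, method: str, k: int = 1) -> list[str]:
        return self.order[method][:k]


def rank_variables(
    table: FeatureTable, methods=RANKING_METHODS, bins: int = 4
) -> RankingResult:
    """Score every feature against the target with each filter method.

    Continuous features are discretized equal-frequency (k = ``bins``)
    first. Only complete rows enter the contingency tables. Rank orders are
    descending by score with ties broken by feature name.
    """
    complete = table.complete()
    y = complete.y.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("ranking requires at least 2 target classes")
    scores = pd.DataFrame(index=list(table.feature_names), columns=list(methods), dtype=float)
    for name in table.feature_names:
        x = discretize_equal_frequency(complete.data[name].to_numpy(dtype=float), k=bins)
        for method in methods:
            scores.loc[name, method] = _SCORERS[method](x, y)
    order = {
        method: sorted(scores.index, key=lambda f: (-scores.loc[f, method], f))
        for method in methods
    }
    return RankingResult(scores=scores, order=order, n_rows=len(complete))


@dataclass(frozen=True)
class EmbeddingResult:
    """2-D t-SNE coordinates of the complete rows, with full seed provenance."""

    coords: np.ndarray  # (n, 2)
    row_index: pd.DataFrame  # metadata + target of the embedded rows
    perplexity: float
    seed: int


def tsne_embed(
    table: FeatureTable, perplexity: float | None = None, seed: int = 0
) -> EmbeddingResult:
    """Embed the complete rows in 2-D with t-SNE (PCA initialization).

    Perplexity defaults to min(30, (n - 1) / 3) and is shrunk with a warning
    when the requested value is infeasible for the row count.
    """
    complete = table.complete()
    n = len(complete)
    if n < 4:
        raise ValueError(f"t-SNE needs at least 4 complete rows, got {n}")
    limit = (n - 1) / 3
    if perplexity is None:
        perplexity = min(30.0, limit)
    elif perplexity >= limit:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} rows; shrunk to {limit:.2f}",
            stacklevel=2,
        )
        perplexity = limit
    x = complete.features.to_numpy(dtype=float)
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        learning_rate="auto",
        random_state=seed,
    )
    coords = tsne.fit_transform(x)
    meta_cols = [c for c in complete.metadata if c in complete.data.columns]
    row_index = complete.data[meta_cols + [complete.target]].copy()
    return EmbeddingResult(coords=coords, row_index=row_index, perplexity=float(perplexity), seed=seed)


@dataclass(frozen=True)
class ClusterResult:
    """K-means labels plus agreement with the known condition labels."""

    labels: np.ndarray
    k: int
    seed: int
    inertia: float
    purity: float | None = None
    adjusted_rand: float | None = None


def cluster_purity(labels: np.ndarray, reference: np.ndarray) -> float:
    """Fraction of rows in their cluster's majority reference class."""
    labels = np.asarray(labels)
    reference = np.asarray(reference)
    total = 0
    for c in np.unique(labels):
        _, counts = np.unique(reference[labels == c], return_counts=True)
        total += counts.max()
    return total / len(labels)


def kmeans_cluster(
    points, k: int = 2, seed: int = 0, restarts: int = 10, reference=None
) -> ClusterResult:
    """Best-inertia K-means labeling over ``restarts`` seeded restarts.

    When reference condition labels are given, the purity (majority-class
    share per cluster) and the adjusted Rand index (chance-corrected
    pair-counting agreement) are reported alongside.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if points.shape[0] < k:
        raise ValueError(f"need at least k={k} rows, got {points.shape[0]}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(points)
    purity = ari = None
    if reference is not None:
        reference = np.asarray(reference)
        purity = cluster_purity(labels, reference)
        ari = float(adjusted_rand_score(reference, labels))
    return ClusterResult(
        labels=labels, k=k, seed=seed, inertia=float(km.inertia_), purity=purity, adjusted_rand=ari
    )


@dataclass(frozen=True)
class ProjectionResult:
    """PCA scores and per-feature axis vectors for a biplot.

    Each feature's axis vector is its loadings on (PC1, PC2); the vector
    points in the direction of increasing feature values in the score plane.
    """

    scores: np.ndarray  # (n, 2)
    loadings: pd.DataFrame  # feature x (PC1, PC2)
    explained_variance_ratio: np.ndarray  # (2,)
    row_index: pd.DataFrame


def pca_projection(table: FeatureTable) -> ProjectionResult:
    """Project the standardized complete rows onto the first two principal
    components. Sign convention: within each component the largest-magnitude
    loading is positive, so repeated runs draw identical biplots."""
    complete = table.complete()
    n = len(complete)
    if n < 2:
        raise ValueError("PCA projection needs at least 2 complete rows")
    x = complete.features.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xz = (x - mean) / sd
    n_comp = min(2, n - 1, xz.shape[1])
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(xz)
    components = pca.components_
    for i in range(components.shape[0]):
        j = np.argmax(np.abs(components[i]))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    if n_comp < 2:  # degenerate: pad a zero second axis
        components = np.vstack([components, np.zeros(xz.shape[1])])
        scores = np.column_stack([scores, np.zeros(n)])
        evr = np.append(pca.explained_variance_ratio_, 0.0)
    else:
        evr = pca.explained_variance_ratio_[:2]
    loadings = pd.DataFrame(
        components[:2].T, index=list(table.feature_names), columns=["PC1", "PC2"]
    )
    meta_cols = [c for c in complete.metadata if c in complete.data.columns]
    row_index = complete.data[meta_cols + [complete.target]].copy()
    return ProjectionResult(
        scores=scores[:, :2],
        loadings=loadings,
        explained_variance_ratio=np.asarray(evr, dtype=float),
        row_index=row_index,
    )
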