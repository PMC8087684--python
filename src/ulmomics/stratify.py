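"""Unsupervised stratification: MAD feature filtering, correlation-distance
hierarchical clustering (UPGMA) and PCA.

MAD here is the raw median absolute deviation (no 1.4826 consistency
factor), applied strictly (">") as a variability filter before clustering.
Clustering uses 1 - Pearson correlation (pairwise-complete) with average
linkage; a Spearman flag is available.  PCA centers features and by default
does not rescale them to unit variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import CohortDesign, ExpressionMatrix

logger = logging.getLogger(__name__)


class StratifyError(ValueError):
    pass


@dataclass
class PcaResult:
    """Sample scores and variance-explained fractions from an SVD of centered data."""

    scores: pd.DataFrame  # samples x components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        ve = self.variance_explained
        if np.any(np.diff(ve) > 1e-12):
            raise StratifyError("variance explained must be non-increasing")


@dataclass
class ClusterResult:
    """Dendrogram for one axis: scipy linkage matrix, labels and leaf order."""

    linkage: np.ndarray
    labels: list[str]
    axis: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> pd.Series:
        """Flat cluster labels (1..k) per item."""
        assignments = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(assignments, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick serialization with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def _walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = _walk(node.left, node.dist)
            right = _walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return _walk(tree, tree.dist) + ";"


def mad_filter(matrix: ExpressionMatrix, threshold: float) -> ExpressionMatrix:
    """Keep features whose raw MAD over non-missing values exceeds threshold strictly."""
    if threshold < 0:
        raise StratifyError("MAD threshold must be nonnegative")
    values = matrix.data.to_numpy(float)
    with np.errstate(all="ignore"):
        med = np.nanmedian(values, axis=1, keepdims=True)
        mad = np.nanmedian(np.abs(values - med), axis=1)
    keep = mad > threshold
    logger.info("MAD > %g filter: %d of %d features retained", threshold, int(keep.sum()), len(keep))
    return ExpressionMatrix(matrix.data.loc[keep], matrix.layer)


def _correlation_distance(data: pd.DataFrame, method: str, min_periods: int = 3) -> np.ndarray:
    corr = data.corr(method=method, min_periods=min_periods)
    if corr.isna().any().any():
        bad = [(a, b) for a in corr.index for b in corr.columns
               if a < b and pd.isna(corr.loc[a, b])]
        raise StratifyError(f"pairs with < {min_periods} co-observed values: {bad[:5]}")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    return squareform(dist, checks=False)


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "samples",
    method: str = "pearson",
    center_features: bool = False,
) -> ClusterResult:
    """UPGMA clustering on 1 - correlation distance (pairwise-complete).

    ``axis="samples"`` clusters columns; ``axis="features"`` clusters rows.
    ``center_features`` subtracts each feature's mean first (the usual
    heatmap convention; it changes sample-sample correlations but is a no-op
    for feature-axis clustering).  scipy's average-linkage merge order is
    deterministic given the distance matrix, so ties break by input order.
    """
    if axis not in ("samples", "features"):
        raise StratifyError(f"axis must be 'samples' or 'features', got {axis!r}")
    values = matrix.data
    if center_features:
        values = values.sub(values.mean(axis=1), axis=0)
    data = values if axis == "samples" else values.T
    if data.shape[1] < 2:
        raise StratifyError("need >= 2 items to cluster")
    condensed = _correlation_distance(data, method)
    linkage = hierarchy.linkage(condensed, method="average")
    return ClusterResult(linkage=linkage, labels=list(data.columns), axis=axis)


def pca(matrix: ExpressionMatrix, scale: str = "none") -> PcaResult:
    """PCA of samples over features via SVD of the feature-centered matrix.

    ``scale="unit-variance"`` additionally divides each feature by its SD
    (ClustVis-style); constant features are dropped in that mode.  Missing
    values are a hard error — filter to complete rows first.
    """
    if scale not in ("none", "unit-variance"):
        raise StratifyError(f"unknown scale mode {scale!r}")
    data = matrix.data
    if data.isna().any().any():
        raise StratifyError("PCA input has missing values; apply a completeness filter first")
    if data.shape[1] < 2:
        raise StratifyError("need >= 2 samples")
    x = data.to_numpy(float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    if scale == "unit-variance":
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = x[:, keep] / sd[keep]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise StratifyError("zero-variance matrix")
    scores = u * s
    n_comp = scores.shape[1]
    return PcaResult(
        scores=pd.DataFrame(scores, index=data.columns, columns=[f"PC{i + 1}" for i in range(n_comp)]),
        variance_explained=(s**2) / total,
    )


def cluster_agreement(assignments: pd.Series, design: CohortDesign) -> float:
    """Fraction of samples whose 2-cluster assignment matches cohort labels,
    maximized over the label swap."""
    cohorts = design.table.loc[assignments.index, "cohort"]
    a, b = design.cohort_pair()
    truth = (cohorts == a).to_numpy()
    pred = (assignments == assignments.iloc[0]).to_numpy()
    agree = float(np.mean(truth == pred))
    return max(agree, 1.0 - agree)
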