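"""Resampling consensus hierarchical clustering and heat-map ordering.

Libraries are clustered on one-minus-Spearman correlation distances with
average (UPGMA) linkage.  Stability comes from consensus over resampled
gene sets: each iteration subsamples 80% of genes without replacement,
re-clusters the libraries, and the co-clustering frequency matrix is
itself clustered once more for the final partition.  DE heat maps order
genes by one-minus-Pearson distance and scale each row to [0, 1].
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin

logger = logging.getLogger(__name__)


class ClusteringError(ValueError):
    pass


def correlation_distance(
    X: np.ndarray, method: str = "spearman", labels: list[str] | None = None
) -> pd.DataFrame:
    """One-minus-correlation distances between the columns of X.

    Rows are features (genes), columns the items to compare (libraries).
    Spearman uses average ranks for ties.  Distances lie in [0, 2].
    A zero-variance column is an error naming the item.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ClusteringError("need at least 3 features per item")
    names = labels if labels is not None else [f"item{i}" for i in range(X.shape[1])]
    if method == "spearman":
        Xr = np.apply_along_axis(rankdata, 0, X)
    elif method == "pearson":
        Xr = X
    else:
        raise ClusteringError(f"unknown method {method!r}")
    sd = Xr.std(axis=0)
    dead = np.where(sd == 0)[0]
    if len(dead):
        raise ClusteringError(
            f"zero-variance item(s): {[names[i] for i in dead]}"
        )
    corr = np.corrcoef(Xr, rowvar=False)
    D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(D, index=names, columns=names)


def hclust_average(D: pd.DataFrame | np.ndarray, k: int):
    """Average-linkage (UPGMA) agglomeration; cut at k clusters.

    Returns (labels, linkage_matrix); labels are 1..k' with
    k' = min(k, n_items).
    """
    if k < 1:
        raise ClusteringError(f"k must be >= 1, got {k}")
    Dm = D.to_numpy() if isinstance(D, pd.DataFrame) else np.asarray(D, float)
    Z = hierarchy.linkage(squareform(Dm, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=min(k, Dm.shape[0]), criterion="maxclust")
    return labels, Z


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering of libraries over resampled gene subsets.

    Parameters
    ----------
    n_clusters : int, default=18
        Clusters for both the per-iteration cut and the final consensus cut.
    n_iterations : int, default=1000
        Resampling iterations.
    subsample_frac : float, default=0.8
        Fraction of genes (features) drawn without replacement per iteration.
    metric : {"spearman", "pearson"}, default="spearman"
        Correlation used for the per-iteration library distances.
    random_state : int or None
        Seed; the same seed reproduces the consensus matrix exactly.

    Attributes
    ----------
    consensus_matrix_ : ndarray (n_items, n_items)
        Co-clustering frequency over iterations; symmetric, unit diagonal.
    labels_ : final partition from average linkage on 1 - consensus.
    linkage_ : scipy linkage matrix of the final consensus tree.
    """

    def __init__(
        self,
        n_clusters: int = 18,
        n_iterations: int = 1000,
        subsample_frac: float = 0.8,
        metric: str = "spearman",
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_iterations = n_iterations
        self.subsample_frac = subsample_frac
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y=None):
        """X is (n_items, n_features): libraries as rows, genes as columns."""
        X = np.asarray(X, dtype=float)
        if self.n_iterations < 1:
            raise ClusteringError("n_iterations must be >= 1")
        n_items, n_genes = X.shape
        n_sub = max(3, math.ceil(self.subsample_frac * n_genes))
        rng = np.random.default_rng(self.random_state)
        co = np.zeros((n_items, n_items))
        for _ in range(self.n_iterations):
            genes = rng.choice(n_genes, size=min(n_sub, n_genes), replace=False)
            D = correlation_distance(X[:, genes].T, method=self.metric)
            labels, _ = hclust_average(D, self.n_clusters)
            same = labels[:, None] == labels[None, :]
            co += same
        # every iteration includes all items, so the denominator is constant
        self.consensus_matrix_ = co / self.n_iterations
        np.fill_diagonal(self.consensus_matrix_, 1.0)
        D_cons = 1.0 - self.consensus_matrix_
        np.fill_diagonal(D_cons, 0.0)
        self.labels_, self.linkage_ = hclust_average(D_cons, self.n_clusters)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_cluster(
    matrix: np.ndarray,
    k: int = 18,
    iterations: int = 1000,
    subsample_frac: float = 0.8,
    seed: int | None = None,
    metric: str = "spearman",
) -> ConsensusClustering:
    """Functional wrapper; ``matrix`` is genes x libraries (on-disk layout)."""
    model = ConsensusClustering(
        n_clusters=k,
        n_iterations=iterations,
        subsample_frac=subsample_frac,
        metric=metric,
        random_state=seed,
    )
    return model.fit(np.asarray(matrix, dtype=float).T)


def heatmap_order(
    de_matrix: pd.DataFrame, gene_method: str = "pearson"
) -> tuple[list[str], pd.DataFrame]:
    """Row ordering and per-row min-max scaling for a DE heat map.

    ``de_matrix`` is genes x groups (e.g. landrace means of normalized
    counts).  Each row is scaled so its minimum maps to 0 and maximum to 1;
    constant rows become all-0.5 with a warning.  Row order comes from the
    leaf order of a one-minus-correlation average-linkage gene dendrogram.
    """
    M = de_matrix.to_numpy(dtype=float)
    lo = M.min(axis=1, keepdims=True)
    rng_ = M.max(axis=1, keepdims=True) - lo
    flat = (rng_ == 0).ravel()
    if flat.any():
        logger.warning(
            "%d constant rows scaled to 0.5: %s",
            int(flat.sum()),
            de_matrix.index[flat].tolist()[:5],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(rng_ > 0, (M - lo) / rng_, 0.5)
    if de_matrix.shape[0] > 2:
        # gene distances computed on non-constant rows; constant rows appended
        ok = ~flat
        if ok.sum() > 2:
            D = correlation_distance(
                M[ok].T, method=gene_method, labels=de_matrix.index[ok].tolist()
            )
            Z = hierarchy.linkage(
                squareform(D.to_numpy(), checks=False), method="average"
            )
            order_ok = hierarchy.leaves_list(Z)
            row_order = de_matrix.index[ok][order_ok].tolist() + de_matrix.index[
                flat
            ].tolist()
        else:
            row_order = de_matrix.index.tolist()
    else:
        row_order = de_matrix.index.tolist()
    scaled_df = pd.DataFrame(
        scaled, index=de_matrix.index, columns=de_matrix.columns
    ).loc[row_order]
    return row_order, scaled_df
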