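"""Sample clustering on the most variable methylation loci.

Loci are ranked by across-sample variance of beta, the top k (default
10,000) are kept to exclude noise and low-information loci, and samples
are clustered agglomeratively on Euclidean distances between their beta
profiles. A covariance-based (Mahalanobis-like whitened) distance mode is
available behind a flag for fidelity experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .methylation import MethMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterResult", "select_top_variance_loci", "hierarchical_cluster"]


@dataclass
class ClusterResult:
    """Dendrogram of samples: scipy linkage matrix, labels, leaf order."""

    linkage: np.ndarray
    labels: list[str]
    distances: pd.DataFrame

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels (1..n_clusters) at a cut of the dendrogram."""
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def select_top_variance_loci(matrix: MethMatrix, k: int = 10000) -> MethMatrix:
    """Keep the k loci with the largest across-sample variance of beta.

    Ties in variance break by (chrom, pos) order. If the matrix has fewer
    than k loci, all are kept with a warning.
    """
    var = matrix.beta.var(axis=1, ddof=1, skipna=True).fillna(-np.inf)
    if matrix.n_loci <= k:
        if matrix.n_loci < k:
            logger.warning(
                "select_top_variance_loci: only %d loci available (< k=%d); keeping all",
                matrix.n_loci,
                k,
            )
        return matrix
    order = np.lexsort((np.arange(len(var)), -var.to_numpy()))
    keep_positions = np.sort(order[:k])
    return matrix.subset_loci(matrix.beta.index[keep_positions])


def hierarchical_cluster(
    matrix: MethMatrix,
    linkage_method: str = "average",
    covariance_mode: bool = False,
) -> ClusterResult:
    """Agglomerative clustering of samples on their beta profiles.

    Distances are Euclidean between sample beta vectors over the loci in
    ``matrix`` (loci with any missing value are dropped first). With
    ``covariance_mode`` the profiles are whitened by the locus-wise
    covariance structure (PCA whitening) before the distance computation.
    """
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples to cluster")
    beta = matrix.beta.dropna(axis=0, how="any")
    x = beta.to_numpy(dtype=float).T  # samples x loci
    if covariance_mode:
        centered = x - x.mean(axis=0, keepdims=True)
        # whiten in sample space (loci >> samples): scale principal axes to unit variance
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        nz = s > 1e-12
        x = u[:, nz] * np.sqrt(max(x.shape[0] - 1, 1))
    d = pdist(x, metric="euclidean")
    z = hierarchy.linkage(d, method=linkage_method)
    dist_df = pd.DataFrame(squareform(d), index=matrix.samples, columns=matrix.samples)
    return ClusterResult(linkage=z, labels=matrix.samples, distances=dist_df)
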