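"""Hierarchical clustering of samples (or genes) with the study's choices.

Distance is 1 - Spearman rank correlation between columns (or plain
Euclidean), linkage is complete (farthest neighbour), which guarantees
monotone merge heights. The 1 - rho transform (rather than 1 - |rho| or
(1 - rho)/2) is the recorded default and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

from .errors import ValidationError


def spearman_distance(matrix: pd.DataFrame, transform: str = "one_minus") -> pd.DataFrame:
    """Pairwise column distance d(i, j) = 1 - rho_spearman(i, j).

    Rank-based, hence invariant under strictly monotone transforms of any
    single column. Constant columns have undefined correlation and raise,
    naming the column.
    """
    if matrix.shape[0] < 3:
        raise ValidationError("spearman distance needs >= 3 rows")
    const = matrix.nunique(axis=0) <= 1
    if const.any():
        raise ValidationError(
            f"constant column {matrix.columns[const.argmax()]!r}: "
            "Spearman correlation undefined"
        )
    rho = spearmanr(matrix.to_numpy(), axis=0).statistic
    if np.ndim(rho) == 0:  # scipy collapses the two-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if transform == "one_minus":
        d = 1.0 - rho
    elif transform == "one_minus_abs":
        d = 1.0 - np.abs(rho)
    elif transform == "half_one_minus":
        d = (1.0 - rho) / 2.0
    else:
        raise ValidationError(f"unknown transform {transform!r}")
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def euclidean_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    d = squareform(pdist(matrix.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Complete-linkage merge tree with scipy linkage encoding.

    ``linkage_matrix`` rows are (left, right, height, size) with the
    standard scipy node numbering over ``labels``.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    distance: str = "unspecified"
    method: str = "complete"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.labels[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Labels for a k-group cut (1..k, scipy maxclust criterion)."""
        assignments = hierarchy.fcluster(self.linkage_matrix, k, criterion="maxclust")
        return pd.Series(assignments, index=self.labels, name="cluster")

    def to_newick(self) -> str:
        """Newick string; branch lengths = parent height - child height."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hcluster(
    distances: pd.DataFrame, method: str = "complete", distance_name: str = ""
) -> Dendrogram:
    """Agglomerative clustering of a symmetric distance matrix."""
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("hcluster requires a symmetric distance matrix")
    condensed = squareform(d, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    return Dendrogram(
        linkage_matrix=Z,
        labels=[str(c) for c in distances.columns],
        distance=distance_name,
        method=method,
    )


def cluster_samples(
    matrix: pd.DataFrame,
    distance: str = "spearman",
    method: str = "complete",
    cut_k: int | None = None,
) -> tuple[Dendrogram, pd.Series | None]:
    """Convenience: distance + linkage + optional k-cut on sample columns."""
    if distance == "spearman":
        d = spearman_distance(matrix)
    elif distance == "euclidean":
        d = euclidean_distance(matrix)
    else:
        raise ValidationError(f"unknown distance {distance!r}")
    dend = hcluster(d, method=method, distance_name=distance)
    labels = dend.cut(cut_k) if cut_k else None
    return dend, labels
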