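"""Correlation-dissimilarity hierarchical clustering of expression matrices.

Rows are proteins/genes, columns are samples.  Pearson correlations are
computed on pairwise-complete observations (missing values allowed), tested
with the usual two-sided t statistic, Bonferroni-corrected over the distinct
off-diagonal pairs, and converted into a dissimilarity

    D = 1 - |r|

so that perfectly correlated OR anti-correlated rows are maximally close.
Agglomerative clustering then runs on D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationResult",
    "DissimilarityMatrix",
    "correlation_matrix",
    "dissimilarity",
    "hierarchical_cluster",
    "linkage_to_newick",
    "read_expression_tsv",
]

MIN_PAIRWISE_OBS = 3


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_obs: pd.DataFrame  # pairwise-complete sample counts


@dataclass
class DissimilarityMatrix:
    D: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.D.to_numpy(dtype=float)
        if values.shape[0] != values.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("dissimilarity matrix must be symmetric")
        finite = values[np.isfinite(values)]
        if ((finite < -1e-12) | (finite > 1 + 1e-12)).any():
            raise ValueError("dissimilarities must lie in [0, 1]")

    @property
    def labels(self) -> list[str]:
        return list(self.D.index)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a row-labelled expression TSV (header = sample names)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def correlation_matrix(
    matrix: pd.DataFrame, min_obs: int = MIN_PAIRWISE_OBS
) -> CorrelationResult:
    """Row-row Pearson correlations on pairwise-complete observations.

    p-values come from the t transform t = r*sqrt((n-2)/(1-r^2)) with n the
    pairwise-complete count; the Bonferroni factor is the number of distinct
    off-diagonal pairs.  Pairs with fewer than ``min_obs`` shared samples,
    or involving a zero-variance row, get NaN r.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < min_obs:
        raise ValueError(f"need >= 2 rows and >= {min_obs} columns")
    # pandas corr() computes pairwise-complete Pearson r
    r = matrix.T.corr(method="pearson", min_periods=min_obs)
    observed = matrix.notna().to_numpy(dtype=float)
    n_obs = observed @ observed.T
    m = matrix.shape[0]
    n_pairs = m * (m - 1) // 2
    rv = r.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df_ = n_obs - 2
        t = rv * np.sqrt(df_ / (1.0 - rv**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df_, 1))
    p = np.where(np.isclose(np.abs(rv), 1.0), 0.0, p)
    p = np.where(np.isnan(rv), np.nan, p)
    np.fill_diagonal(p, 0.0)
    p_adj = np.minimum(p * n_pairs, 1.0)
    idx = matrix.index
    return CorrelationResult(
        r=r,
        p=pd.DataFrame(p, index=idx, columns=idx),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=idx),
        n_obs=pd.DataFrame(n_obs.astype(int), index=idx, columns=idx),
    )


def dissimilarity(r: pd.DataFrame) -> DissimilarityMatrix:
    """D = 1 - |r| elementwise; undefined correlations propagate as NaN."""
    rv = r.to_numpy(dtype=float)
    finite = rv[np.isfinite(rv)]
    if ((finite < -1 - 1e-9) | (finite > 1 + 1e-9)).any():
        raise ValueError("correlations must lie in [-1, 1]")
    D = 1.0 - np.abs(rv)
    D = np.clip(D, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(pd.DataFrame(D, index=r.index, columns=r.columns))


def hierarchical_cluster(
    dissim: DissimilarityMatrix,
    k: int,
    linkage: str = "complete",
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering on a precomputed dissimilarity.

    Undefined entries (pairs below the minimum overlap) are treated as
    maximally dissimilar (D = 1).  Returns the k-cut labels (1..k,
    renumbered in order of first appearance) and the scipy linkage matrix.
    """
    n = dissim.D.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    values = dissim.D.to_numpy(dtype=float).copy()
    values[np.isnan(values)] = 1.0
    np.fill_diagonal(values, 0.0)
    if n == 1:
        return pd.Series([1], index=dissim.D.index, name="cluster"), np.empty((0, 4))
    condensed = squareform(values, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels.append(relabel[lab])
    return pd.Series(labels, index=dissim.D.index, name="cluster"), Z


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    if len(Z) == 0:
        return f"{labels[0]};" if labels else ";"
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - (node.dist if not node.is_leaf() else 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"
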