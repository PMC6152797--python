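"""Correlation structure of per-transcript mRNA features.

Features such as half-life, translation efficiency (TE), polyA tail length,
codon adaptation index (CAI), tRNA-adaptation-based optimality (nTE),
abundance, UTR lengths, GC content and ORF length arrive precomputed, one
column per feature.  Pairwise Spearman rank correlations are computed on
pairwise-complete observations (feature sets from heterogeneous external
datasets rarely cover identical transcript sets), and the correlation
matrix is hierarchically clustered on the Euclidean distances between its
rows (average linkage by default) to group features that share correlation
structure.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

MIN_PAIR_OVERLAP = 3


class InsufficientOverlapError(ValueError):
    """A feature pair shares fewer than 3 non-missing transcripts."""


def spearman_matrix(tbl: pd.DataFrame, min_overlap: int = MIN_PAIR_OVERLAP) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix with average-rank ties.

    ``tbl`` holds one row per transcript, one numeric column per feature;
    missing cells are allowed.  Each pair is computed over its complete
    observations; any pair sharing fewer than ``min_overlap`` transcripts
    raises, naming the pair.
    """
    if tbl.shape[1] < 2:
        raise ValueError("need at least 2 features")
    notna = tbl.notna()
    for i, a in enumerate(tbl.columns):
        for b in tbl.columns[i + 1:]:
            n = int((notna[a] & notna[b]).sum())
            if n < min_overlap:
                raise InsufficientOverlapError(
                    f"features {a!r} and {b!r} share only {n} transcripts "
                    f"(need >= {min_overlap})")
    m = tbl.corr(method="spearman", min_periods=min_overlap)
    np.fill_diagonal(m.values, 1.0)
    return m


def cluster_features(matrix: pd.DataFrame, method: str = "average"):
    """Hierarchically cluster a correlation matrix on row Euclidean distances.

    Returns (linkage, leaf_order): a scipy linkage array and the feature
    names in dendrogram leaf order.  Features are pre-sorted lexicographically
    so equal-height merges resolve deterministically.
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(matrix.values, matrix.values.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    order = sorted(matrix.columns)
    m = matrix.loc[order, order]
    if len(order) < 2:
        return np.empty((0, 4)), list(order)
    dist = pdist(m.to_numpy(dtype=float), metric="euclidean")
    linkage = hierarchy.linkage(dist, method=method)
    leaves = hierarchy.leaves_list(linkage)
    return linkage, [order[i] for i in leaves]


class FeatureCorrelation(BaseEstimator):
    """Spearman correlation + hierarchical clustering of feature columns.

    Parameters
    ----------
    linkage_method : str
        scipy linkage method over Euclidean row distances (default UPGMA /
        "average").
    min_overlap : int
        Minimum pairwise-complete transcripts per feature pair.

    Attributes
    ----------
    matrix_ : pandas.DataFrame
        Symmetric Spearman matrix with unit diagonal.
    linkage_ : numpy.ndarray
        scipy linkage array (merge heights in column 2).
    leaf_order_ : list of str
        Feature names in dendrogram leaf order.
    """

    def __init__(self, linkage_method: str = "average", min_overlap: int = MIN_PAIR_OVERLAP):
        self.linkage_method = linkage_method
        self.min_overlap = min_overlap

    def fit(self, X: pd.DataFrame, y=None):
        self.matrix_ = spearman_matrix(X, self.min_overlap)
        self.linkage_, self.leaf_order_ = cluster_features(self.matrix_, self.linkage_method)
        return self

    def plot(self, path=None):
        """Render the clustered correlation matrix as a diverging heatmap."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = self.leaf_order_
        m = self.matrix_.loc[order, order].to_numpy(dtype=float).copy()
        np.fill_diagonal(m, np.nan)  # self-correlations rendered gray
        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(order),) * 2)
        cmap = plt.get_cmap("PuOr_r").copy()
        cmap.set_bad("lightgray")
        im = ax.imshow(m, vmin=-1, vmax=1, cmap=cmap)
        ax.set_xticks(range(len(order)), order, rotation=90)
        ax.set_yticks(range(len(order)), order)
        fig.colorbar(im, ax=ax, label="Spearman rho")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
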