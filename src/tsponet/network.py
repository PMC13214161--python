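"""Single-subject similarity networks.

Kinetic features are standardized with a robust z-score (median/MAD) pooled
over all scans and regions of a tracer group, so each of the four features
contributes comparably to the Euclidean distance while between-region
contrast is preserved. The similarity between regions i and j is the
normalized inverse distance

    S_ij = 1 / (1 + d_ij),   d_ij = || x_i - x_j ||_2

which lies in (0, 1] and equals 1 only for identical feature vectors. The
R(R-1)/2 strictly-upper-triangle entries in row-major order form the
canonical edge vector (3741 edges for the 87-region atlas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "RobustMadScaler", "SimilarityMatrix", "EdgeVector", "robust_standardize",
    "build_similarity", "to_edge_vector", "edge_vector_to_matrix",
    "edge_index_pairs", "intersubject_correlation", "rank_correlation_matrix",
]


class RobustMadScaler(TransformerMixin, BaseEstimator):
    """Robust z-score transformer: (x - median) / MAD per feature column.

    The median and MAD are computed by pooling every row of every sample
    passed to :meth:`fit` (all scans and all regions of a tracer group).
    The MAD is the raw median absolute deviation, with no normal-consistency
    factor.

    Attributes
    ----------
    center_ : ndarray of shape (n_features,)
        Per-feature pooled median.
    scale_ : ndarray of shape (n_features,)
        Per-feature pooled MAD.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with at least 2 pooled rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature pool")
        self.center_ = np.median(X, axis=0)
        self.scale_ = np.median(np.abs(X - self.center_), axis=0)
        degenerate = np.flatnonzero(self.scale_ == 0)
        if degenerate.size:
            names = [FEATURE_NAMES[i] if i < len(FEATURE_NAMES) else str(i)
                     for i in degenerate]
            raise ValueError(f"degenerate dispersion (MAD = 0) for features {names}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "center_")
        X = np.asarray(X, dtype=float)
        return (X - self.center_) / self.scale_

    def inverse_transform(self, X):
        check_is_fitted(self, "center_")
        return np.asarray(X, dtype=float) * self.scale_ + self.center_


def robust_standardize(tables):
    """Standardize all feature tables of one tracer group with a shared
    pooled median/MAD.

    Returns ``(standardized_tables, scaler)``; the fitted scaler can be
    reapplied to later scans of the same group. Tables that are already
    standardized are rejected so the transform is applied exactly once.
    """
    tables = list(tables)
    if any(t.standardized for t in tables):
        raise ValueError("input tables are already standardized")
    pooled = np.vstack([t.values for t in tables])
    scaler = RobustMadScaler().fit(pooled)
    out = [FeatureTable(t.scan_id, scaler.transform(t.values),
                        roi_names=t.roi_names, standardized=True)
           for t in tables]
    return out, scaler


@dataclass
class SimilarityMatrix:
    """Symmetric region-by-region similarity with unit diagonal."""

    scan_id: str
    values: np.ndarray
    roi_names: tuple = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity diagonal must be 1")
        if np.any(v <= 0) or np.any(v > 1 + 1e-12):
            raise ValueError("similarities must lie in (0, 1]")
        if self.roi_names and len(self.roi_names) != v.shape[0]:
            raise ValueError("roi_names length does not match matrix size")

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]


@dataclass
class EdgeVector:
    """Canonical strictly-upper-triangle vectorization of a similarity
    matrix (row-major over i < j)."""

    scan_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("edge vector must be 1-D")


def build_similarity(features, scan_id: str = "") -> SimilarityMatrix:
    """Inverse-Euclidean similarity matrix from standardized regional
    features.

    Accepts a standardized :class:`FeatureTable` or a raw [R x k] array
    (assumed already standardized).
    """
    roi_names = ()
    if isinstance(features, FeatureTable):
        if not features.standardized:
            raise ValueError("features must be standardized before building "
                             "similarity (robust_standardize)")
        scan_id = scan_id or features.scan_id
        roi_names = features.roi_names
        features = features.values
    x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    s = 1.0 / (1.0 + squareform(pdist(x, metric="euclidean")))
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(scan_id=scan_id, values=s, roi_names=roi_names)


def edge_index_pairs(n_roi: int) -> np.ndarray:
    """[n_edges x 2] array of (i, j) region indices in canonical edge
    order."""
    iu = np.triu_indices(n_roi, k=1)
    return np.column_stack(iu)


def to_edge_vector(matrix: SimilarityMatrix) -> EdgeVector:
    """Vectorize the strict upper triangle in canonical order."""
    v = matrix.values
    iu = np.triu_indices(v.shape[0], k=1)
    return EdgeVector(scan_id=matrix.scan_id, values=v[iu])


def edge_vector_to_matrix(edges, roi_names=(), scan_id: str = "") -> SimilarityMatrix:
    """Rebuild the symmetric similarity matrix from a canonical edge
    vector."""
    if isinstance(edges, EdgeVector):
        scan_id = scan_id or edges.scan_id
        edges = edges.values
    edges = np.asarray(edges, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * edges.size)) / 2))
    if n * (n - 1) // 2 != edges.size:
        raise ValueError(f"edge vector length {edges.size} is not R(R-1)/2")
    m = np.eye(n)
    iu = np.triu_indices(n, k=1)
    m[iu] = edges
    m[(iu[1], iu[0])] = edges
    return SimilarityMatrix(scan_id=scan_id, values=m, roi_names=roi_names)


def rank_correlation_matrix(vectors: np.ndarray) -> np.ndarray:
    """Pairwise Spearman correlation between the rows of ``vectors``."""
    vectors = np.asarray(vectors, dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, vectors)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant edge vectors (rank correlation undefined) "
                         f"at rows {bad.tolist()}")
    return np.corrcoef(ranks)


def intersubject_correlation(edge_vectors, groups=None):
    """Subject-by-subject Spearman correlation of edge vectors, with
    median +/- MAD summaries per (and between) requested groupings.

    Parameters
    ----------
    edge_vectors : sequence of EdgeVector or 2-D array
    groups : sequence of hashable, optional
        One label per vector (e.g. tracer or site). Summaries are computed
        for every within-group and between-group label pair.

    Returns
    -------
    rho : ndarray [n x n]
    summaries : DataFrame with columns group_a, group_b, median, mad, n_pairs
    """
    ids = None
    if len(edge_vectors) and isinstance(edge_vectors[0], EdgeVector):
        ids = [e.scan_id for e in edge_vectors]
        mat = np.vstack([e.values for e in edge_vectors])
    else:
        mat = np.asarray(edge_vectors, dtype=float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 edge vectors")
    rho = rank_correlation_matrix(mat)

    rows = []
    if groups is not None:
        groups = np.asarray(groups)
        labels = sorted(set(groups.tolist()))
        iu = np.triu_indices(mat.shape[0], k=1)
        for a_i, a in enumerate(labels):
            for b in labels[a_i:]:
                mask = ((groups[iu[0]] == a) & (groups[iu[1]] == b)) | \
                       ((groups[iu[0]] == b) & (groups[iu[1]] == a))
                vals = rho[iu][mask]
                if vals.size == 0:
                    continue
                med = float(np.median(vals))
                rows.append({"group_a": a, "group_b": b, "median": med,
                             "mad": float(np.median(np.abs(vals - med))),
                             "n_pairs": int(vals.size)})
    else:
        iu = np.triu_indices(mat.shape[0], k=1)
        vals = rho[iu]
        med = float(np.median(vals))
        rows.append({"group_a": "all", "group_b": "all", "median": med,
                     "mad": float(np.median(np.abs(vals - med))),
                     "n_pairs": int(vals.size)})
    summaries = pd.DataFrame(rows)
    if ids is not None:
        rho = pd.DataFrame(rho, index=ids, columns=ids).to_numpy()
    return rho, summaries
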