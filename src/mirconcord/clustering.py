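"""Per-platform miRNA clustering and cross-platform cluster concordance.

Each platform's miRNA-by-sample matrix (z-scored CTs) is clustered with
Ward's minimum-variance agglomeration on Euclidean distances; the number of
clusters is chosen by the Mojena stopping rule (first fusion height
exceeding mean + k * sd of all fusion heights) and the partition is then
refined by k-means seeded at the Ward-cluster centroids, which keeps the
whole pipeline deterministic.  Partitions from different platforms are
compared by optimal one-to-one cluster matching on the shared-membership
contingency table; the percentage of miRNAs landing outside their matched
reference cluster is the misassignment rate.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _sch
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array

from .io import CtTable, collapse_replicates

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "ClusterConcordance",
    "MojenaWardKMeans",
    "build_expression_matrix",
    "build_expression_matrices",
    "ward_dendrogram",
    "mojena_k",
    "assign_clusters",
    "cluster_concordance",
]

MOJENA_CONSTANT = 1.25  # classical recommended value for the stopping rule


@dataclasses.dataclass(frozen=True)
class ExpressionMatrix:
    """miRNA-by-sample expression matrix for one platform.

    ``values`` has miRNA rows and sample columns with no missing entries
    (imputed where needed); ``imputed`` marks the cells that were filled
    with the row mean of the observed entries.
    """

    platform: object
    values: pd.DataFrame
    imputed: pd.DataFrame

    @property
    def mirnas(self) -> list:
        return list(self.values.index)


class EmptyMatrixError(ValueError):
    """Every miRNA row was removed by the missing-data filter."""


def build_expression_matrices(
    table: CtTable,
    missing_threshold: float = 0.15,
    pooled_filter: bool = True,
    zscore: bool = True,
) -> dict:
    """Per-platform expression matrices with a shared missing-data filter.

    Replicates are collapsed to their mean per (platform, sample, mirna).
    miRNAs whose missing fraction exceeds ``missing_threshold`` are removed
    — judged over the cells of all platforms pooled (default) or within
    each platform (``pooled_filter=False``).  Remaining missing entries are
    replaced by the row (miRNA) mean of the observed entries.  With
    ``zscore=True`` (default) each platform's observed values are
    standardized (mean 0, sd 1 over all retained observed cells) before
    imputation, matching the scale used in the cross-platform analyses.
    """
    wide = collapse_replicates(table).unstack("platform")
    wide.index.names = ["sample", "mirna"]
    cells = wide.stack(future_stack=True)  # (sample, mirna, platform) -> value
    miss = cells.isna().groupby(level="mirna").mean()
    if pooled_filter:
        keep = miss[miss <= missing_threshold].index
        keep_by_platform = {p: keep for p in wide.columns}
    else:
        keep_by_platform = {}
        for p in wide.columns:
            mp = wide[p].isna().groupby(level="mirna").mean()
            keep_by_platform[p] = mp[mp <= missing_threshold].index
    out = {}
    for p in wide.columns:
        mat = wide[p].unstack("sample")  # mirna x sample
        mat = mat.loc[mat.index.intersection(keep_by_platform[p])]
        out[p] = _finish_matrix(p, mat, zscore)
    return out


def build_expression_matrix(
    table: CtTable,
    platform,
    missing_threshold: float = 0.15,
    pooled_filter: bool = True,
    zscore: bool = True,
) -> ExpressionMatrix:
    """One platform's :class:`ExpressionMatrix` (see
    :func:`build_expression_matrices` for the filtering rules)."""
    mats = build_expression_matrices(
        table, missing_threshold=missing_threshold,
        pooled_filter=pooled_filter, zscore=zscore,
    )
    if platform not in mats:
        raise KeyError(f"platform {platform!r} not in table")
    return mats[platform]


def _finish_matrix(platform, mat: pd.DataFrame, zscore: bool) -> ExpressionMatrix:
    # rows with no observed entry at all cannot be imputed
    empty_rows = mat.isna().all(axis=1)
    if empty_rows.any():
        warnings.warn(
            f"platform {platform!r}: dropping {int(empty_rows.sum())} miRNA(s) "
            "with no observed values", stacklevel=3,
        )
        mat = mat.loc[~empty_rows]
    if mat.empty:
        raise EmptyMatrixError(
            f"platform {platform!r}: all miRNA rows removed by the missing-data filter"
        )
    if zscore:
        obs = mat.stack()
        mat = (mat - obs.mean()) / obs.std(ddof=1)
    imputed = mat.isna()
    filled = mat.apply(lambda row: row.fillna(row.mean()), axis=1)
    return ExpressionMatrix(platform=platform, values=filled, imputed=imputed)


# ---------------------------------------------------------------------------
# Ward / Mojena / k-means


def ward_dendrogram(matrix) -> np.ndarray:
    """Ward-linkage merge sequence (scipy linkage matrix) on Euclidean rows.

    Accepts an :class:`ExpressionMatrix`, DataFrame or 2-D array with one
    row per miRNA.  Fusion heights are non-decreasing along the sequence.
    """
    X = _as_array(matrix)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to build a dendrogram")
    return _sch.linkage(X, method="ward", metric="euclidean")


def mojena_k(dendrogram: np.ndarray, k_const: float = MOJENA_CONSTANT) -> int:
    """Cluster count by the Mojena stopping rule.

    Scanning the fusion heights a_1 <= ... <= a_{n-1}, the rule flags the
    merges whose height strictly exceeds mean(a) + k_const * sd(a) (sample
    sd).  Cutting the tree just below the lowest flagged merge leaves
    ``#flagged + 1`` clusters; with no flagged merge the rule returns 1.
    Larger ``k_const`` never yields more clusters.
    """
    heights = np.asarray(dendrogram)[:, 2]
    if heights.size == 0:
        return 1
    sd = heights.std(ddof=1) if heights.size > 1 else 0.0
    if not np.isfinite(sd):
        sd = 0.0
    bound = heights.mean() + k_const * sd
    flagged = int((heights > bound).sum())
    n_leaves = heights.size + 1
    return min(flagged + 1, n_leaves) if flagged else 1


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    """Final partition of one platform's miRNAs.

    ``assignment`` maps miRNA -> cluster label in 1..k; ``trace`` records
    how the partition was produced (Mojena constant, k-means iterations,
    number of labels changed from the Ward cut).
    """

    platform: object
    k: int
    assignment: pd.Series
    trace: dict


def assign_clusters(
    matrix, k: int, dendrogram: np.ndarray | None = None, platform=None
) -> ClusterResult:
    """k-means partition initialized at the Ward-cut centroids.

    The Ward tree is cut into ``k`` clusters, their centroids seed a single
    deterministic k-means run, and the converged assignment is returned.
    (k-means can only lower the within-cluster sum of squares the Ward cut
    already minimizes greedily; with sklearn's k-means no cluster can end
    up empty, as points are relocated to keep all k populated.)
    """
    X = _as_array(matrix)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    index = matrix.values.index if isinstance(matrix, ExpressionMatrix) else (
        matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(n)
    )
    if platform is None and isinstance(matrix, ExpressionMatrix):
        platform = matrix.platform
    if k == n:
        labels = np.arange(1, n + 1)
        return ClusterResult(platform, k, pd.Series(labels, index=index),
                             {"kmeans_iterations": 0, "changed_from_ward": 0})
    if dendrogram is None:
        dendrogram = ward_dendrogram(X)
    ward_labels = _sch.fcluster(dendrogram, t=k, criterion="maxclust")
    uniq = np.unique(ward_labels)
    centroids = np.vstack([X[ward_labels == c].mean(axis=0) for c in uniq])
    km = KMeans(n_clusters=len(uniq), init=centroids, n_init=1, max_iter=300)
    km_labels = km.fit_predict(X)
    # relabel so cluster ids follow the Ward cut where possible
    labels = km_labels + 1
    changed = int((labels != _align_to(ward_labels, labels)).sum())
    assignment = pd.Series(labels, index=index)
    return ClusterResult(
        platform, int(len(uniq)), assignment,
        {"kmeans_iterations": int(km.n_iter_), "changed_from_ward": changed},
    )


def _align_to(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Relabel ``ref`` onto ``other``'s label set by maximal overlap."""
    ref_ids = np.unique(ref)
    other_ids = np.unique(other)
    cont = np.zeros((len(ref_ids), len(other_ids)), dtype=int)
    for i, a in enumerate(ref_ids):
        for j, b in enumerate(other_ids):
            cont[i, j] = int(((ref == a) & (other == b)).sum())
    ri, cj = linear_sum_assignment(-cont)
    mapping = {ref_ids[i]: other_ids[j] for i, j in zip(ri, cj)}
    return np.array([mapping.get(v, -1) for v in ref])


class MojenaWardKMeans(ClusterMixin, BaseEstimator):
    """Ward + Mojena + k-means clusterer with the sklearn estimator API.

    Parameters
    ----------
    k_const : float, default 1.25
        Mojena stopping-rule constant; larger values yield fewer clusters.
    n_clusters : int or None
        Fix the cluster count instead of using the Mojena rule.

    Attributes
    ----------
    linkage_ : (n-1, 4) ndarray
        Ward merge sequence (scipy linkage format).
    mojena_threshold_ : float
        mean + k_const * sd of the fusion heights.
    n_clusters_ : int
        Selected cluster count.
    labels_ : ndarray of int
        0-based cluster labels (sklearn convention).
    """

    def __init__(self, k_const: float = MOJENA_CONSTANT,
                 n_clusters: int | None = None):
        self.k_const = k_const
        self.n_clusters = n_clusters

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.linkage_ = _sch.linkage(X, method="ward", metric="euclidean")
        heights = self.linkage_[:, 2]
        sd = heights.std(ddof=1) if heights.size > 1 else 0.0
        self.mojena_threshold_ = float(heights.mean() + self.k_const * sd)
        self.n_clusters_ = (
            int(self.n_clusters) if self.n_clusters is not None
            else mojena_k(self.linkage_, self.k_const)
        )
        result = assign_clusters(pd.DataFrame(X), self.n_clusters_,
                                 dendrogram=self.linkage_)
        self.labels_ = result.assignment.to_numpy() - 1
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# Cross-platform concordance


@dataclasses.dataclass(frozen=True)
class ClusterConcordance:
    """Agreement of one platform's partition with the reference partition."""

    reference_platform: object
    other_platform: object
    mapping: dict  # other cluster label -> matched reference label (or None)
    concordant: pd.Series  # per shared miRNA
    n_shared: int
    misassigned_pct: float


def cluster_concordance(
    reference: ClusterResult, other: ClusterResult, mode: str = "optimal"
) -> ClusterConcordance:
    """Score a partition against the reference platform's partition.

    Comparison clusters are matched to reference clusters on the
    shared-membership contingency table; a miRNA is concordant when its
    comparison cluster maps to its reference cluster, and
    ``misassigned_pct`` is the complement over the shared miRNAs.  The
    score is invariant under relabeling of either partition.

    Parameters
    ----------
    mode
        ``"optimal"`` (default): one-to-one matching maximizing total
        overlap (Hungarian assignment).  ``"literal"``: each comparison
        cluster maps to the reference cluster it shares most members with,
        provided they share at least two; many-to-one mappings are allowed.
    """
    shared = reference.assignment.index.intersection(other.assignment.index)
    if len(shared) < 2:
        raise ValueError("partitions share fewer than 2 miRNAs")
    ref = reference.assignment.loc[shared]
    oth = other.assignment.loc[shared]
    cont = pd.crosstab(oth, ref)
    if mode == "optimal":
        padded = cont.to_numpy()
        n_r, n_c = padded.shape
        size = max(n_r, n_c)
        square = np.zeros((size, size), dtype=int)
        square[:n_r, :n_c] = padded
        ri, cj = linear_sum_assignment(-square)
        mapping = {}
        for i, j in zip(ri, cj):
            if i < n_r:
                mapping[cont.index[i]] = cont.columns[j] if j < n_c else None
    elif mode == "literal":
        mapping = {}
        for lab in cont.index:
            best = cont.loc[lab].idxmax()
            mapping[lab] = best if cont.loc[lab, best] >= 2 else None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    concordant = pd.Series(
        [mapping.get(o) == r for o, r in zip(oth, ref)], index=shared
    )
    mis = 100.0 * (1.0 - concordant.mean())
    return ClusterConcordance(
        reference_platform=reference.platform,
        other_platform=other.platform,
        mapping=mapping,
        concordant=concordant,
        n_shared=len(shared),
        misassigned_pct=float(mis),
    )


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, ExpressionMatrix):
        X = matrix.values.to_numpy(dtype=float)
    elif isinstance(matrix, pd.DataFrame):
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D miRNA-by-sample matrix")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing entries; impute first")
    return X
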