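"""Clustering cancer genomes on principal components of the feature matrix.

The workflow mirrors the hierarchical-clustering-on-principal-components
(HCPC) scheme: scale the 42 features to zero mean and unit variance
(population convention, denominator N), fit a PCA, keep the smallest number
of components explaining at least 80% of the variance, Ward-cluster the
retained scores (Ward.D2: merge cost equals the increase in within-cluster
sum of squares on Euclidean distances), and consolidate the cut with k-means
started from the hierarchical centroids for at most 10 iterations.  Feature-
cluster associations use the v-test — a signed standardized comparison of a
cluster's feature mean to the cohort mean — with Benjamini-Yekutieli
correction over all cluster x feature tests jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from scipy.stats import norm

from .features import FeatureMatrix
from .stats import benjamini_yekutieli

log = logging.getLogger(__name__)


def scale_features(matrix: FeatureMatrix | pd.DataFrame):
    """Scale columns to zero mean and unit *population* variance.

    Returns (scaled DataFrame, means, scales).  Constant columns get scale 1
    (so they become all-zero) with a warning.
    """
    data = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    if len(data) < 2:
        raise ValueError("scaling requires at least 2 samples")
    means = data.mean(axis=0)
    scales = data.std(axis=0, ddof=0)
    constant = scales[scales == 0].index.tolist()
    if constant:
        log.warning("constant features scaled with unit scale: %s", constant)
        scales = scales.replace(0.0, 1.0)
    return (data - means) / scales, means, scales


@dataclass
class PCAModel:
    """PCA transform plus the >=80%-variance component selection.

    ``loadings`` columns are the orthonormal principal axes (features x
    components); ``feature_contributions`` gives each feature's percentage
    contribution to each component (squared loading x 100).  Per-component
    sign is fixed so the largest-magnitude loading is positive.
    """

    feature_means: pd.Series
    feature_scales: pd.Series
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    n_selected: int
    variance_threshold: float = 0.80

    @property
    def feature_contributions(self) -> pd.DataFrame:
        return 100.0 * self.loadings**2

    def transform(self, features: pd.DataFrame, n_components: Optional[int] = None) -> np.ndarray:
        """Project (unscaled) feature rows onto the first components."""
        m = self.n_selected if n_components is None else n_components
        scaled = (features[self.loadings.index] - self.feature_means) / self.feature_scales
        return scaled.to_numpy() @ self.loadings.to_numpy()[:, :m]


def fit_pca(
    scaled: pd.DataFrame,
    variance_threshold: float = 0.80,
    means: Optional[pd.Series] = None,
    scales: Optional[pd.Series] = None,
) -> PCAModel:
    """Fit PCA on an already-scaled matrix and select components to >=80% variance.

    Rank-deficient input simply retains the available rank.  ``means`` and
    ``scales`` (from :func:`scale_features`) are stored so new samples can be
    projected; identity scaling is assumed when omitted.
    """
    from sklearn.decomposition import PCA

    X = scaled.to_numpy(dtype=float)
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    pca.fit(X)
    comps = pca.components_  # (M, p), rows orthonormal
    # Deterministic sign: largest-|loading| feature positive in each component.
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    evr = pca.explained_variance_ratio_
    n_selected = int(np.searchsorted(np.cumsum(evr), variance_threshold) + 1)
    n_selected = min(n_selected, len(evr))
    cols = [f"PC{i + 1}" for i in range(comps.shape[0])]
    if means is None:
        means = pd.Series(0.0, index=scaled.columns)
    if scales is None:
        scales = pd.Series(1.0, index=scaled.columns)
    return PCAModel(
        feature_means=means,
        feature_scales=scales,
        loadings=pd.DataFrame(comps.T, index=scaled.columns, columns=cols),
        explained_variance_ratio=evr,
        n_selected=n_selected,
        variance_threshold=variance_threshold,
    )


def hierarchical_cluster(pc_scores: np.ndarray, k: int):
    """Ward-linkage clustering of PC scores, cut into k groups.

    Returns (assignments, linkage_record).  Cluster ids are relabeled 0..k-1
    in order of first appearance, which makes the labeling deterministic
    under scipy's deterministic (lowest-index) tie-breaking.
    """
    n = len(pc_scores)
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")
    Z = linkage(pc_scores, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _relabel(raw), Z


def _relabel(labels: np.ndarray) -> np.ndarray:
    order = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        out[i] = order.setdefault(lab, len(order))
    return out


def between_cluster_variance(scores: np.ndarray, assignments: np.ndarray) -> float:
    """(1/N) sum_c n_c ||mu_c - mu||^2 — the between-group share of total variance."""
    mu = scores.mean(axis=0)
    total = 0.0
    for c in np.unique(assignments):
        member = scores[assignments == c]
        total += len(member) * float(((member.mean(axis=0) - mu) ** 2).sum())
    return total / len(scores)


@dataclass
class ClusterModel:
    k: int
    assignments: pd.Series  # sample_id -> cluster id
    centroids: np.ndarray  # k x n_selected
    between_cluster_variance: float
    variance_history: list[float] = field(default_factory=list)
    linkage_record: Optional[np.ndarray] = None


def kmeans_consolidate(
    pc_scores: np.ndarray,
    initial_assignments: np.ndarray,
    max_iter: int = 10,
    sample_ids: Optional[Sequence[str]] = None,
    linkage_record: Optional[np.ndarray] = None,
) -> ClusterModel:
    """Lloyd k-means started from the centroids of the given partition.

    At most ``max_iter`` passes of (assign to nearest centroid, recompute
    centroids).  Because each pass cannot increase the within-cluster sum of
    squares and total variance is fixed, the between-cluster variance is
    non-decreasing across iterations (``variance_history`` records it).  A
    cluster emptied during iteration keeps its previous centroid.
    """
    X = np.asarray(pc_scores, dtype=float)
    assignments = np.asarray(initial_assignments).copy()
    ks = np.unique(assignments)
    centroids = np.vstack([X[assignments == c].mean(axis=0) for c in ks])
    remap = {c: i for i, c in enumerate(ks)}
    assignments = np.array([remap[c] for c in assignments])
    history = [between_cluster_variance(X, assignments)]
    for _ in range(max_iter):
        new_assign = np.argmin(cdist(X, centroids), axis=1)
        for c in range(len(centroids)):
            members = X[new_assign == c]
            if len(members):
                centroids[c] = members.mean(axis=0)
            else:
                log.warning("cluster %d emptied during consolidation; centroid kept", c)
        if np.array_equal(new_assign, assignments):
            break
        assignments = new_assign
        history.append(between_cluster_variance(X, assignments))
    ids = pd.RangeIndex(len(X)) if sample_ids is None else pd.Index(sample_ids)
    return ClusterModel(
        k=len(centroids),
        assignments=pd.Series(assignments, index=ids, name="cluster"),
        centroids=centroids,
        between_cluster_variance=history[-1],
        variance_history=history,
        linkage_record=linkage_record,
    )


def cluster_cohort(
    matrix: FeatureMatrix,
    k: int,
    variance_threshold: float = 0.80,
    max_iter: int = 10,
) -> tuple[PCAModel, ClusterModel]:
    """Full pipeline: scale -> PCA -> Ward on selected PCs -> k-means consolidation."""
    scaled, means, scales = scale_features(matrix)
    pca = fit_pca(scaled, variance_threshold, means, scales)
    scores = pca.transform(matrix.data)
    initial, Z = hierarchical_cluster(scores, k)
    model = kmeans_consolidate(scores, initial, max_iter,
                               sample_ids=matrix.sample_ids, linkage_record=Z)
    return pca, model


@dataclass
class AssociationResult:
    cluster: int
    feature: str
    v_statistic: float
    p_raw: float
    p_adjusted: float
    direction: str  # "positive" / "negative" / "none"


def vtest_associations(
    matrix: FeatureMatrix | pd.DataFrame,
    assignments: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """v-test of every (cluster, feature) pair, BY-corrected jointly.

    For feature x and cluster c of size n_c in a cohort of N,
    v = (mean_c - mean) / sqrt((var / n_c) * (N - n_c) / (N - 1)) with
    population variance; the two-sided p-value comes from the standard
    normal.  Direction is "none" whenever adjusted p > alpha.
    """
    data = matrix.data if isinstance(matrix, FeatureMatrix) else matrix
    labels = np.asarray(assignments.values if isinstance(assignments, pd.Series) else assignments)
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("v-test needs at least 2 clusters")
    N = len(data)
    X = data.to_numpy(dtype=float)
    grand_mean = X.mean(axis=0)
    grand_var = X.var(axis=0, ddof=0)
    rows = []
    for c in clusters:
        member = X[labels == c]
        n_c = len(member)
        if n_c == N:
            raise ValueError("a single all-encompassing cluster has no contrast")
        se = np.sqrt(grand_var / n_c * (N - n_c) / (N - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (member.mean(axis=0) - grand_mean) / se
        v = np.where(se == 0, 0.0, v)
        p = 2 * norm.sf(np.abs(v))
        for j, feat in enumerate(data.columns):
            rows.append((int(c), feat, float(v[j]), float(p[j])))
    out = pd.DataFrame(rows, columns=["cluster", "feature", "v_statistic", "p_raw"])
    out["p_adjusted"] = benjamini_yekutieli(out["p_raw"].to_numpy())
    out["direction"] = np.where(
        out["p_adjusted"] > alpha, "none",
        np.where(out["v_statistic"] > 0, "positive", "negative"),
    )
    return out


def jaccard(a: set, b: set) -> float:
    union = a | b
    return len(a & b) / len(union) if union else 0.0


@dataclass
class ClusterTree:
    """Cluster memberships across resolutions, with cross-resolution flow edges.

    ``edges`` link clusters at consecutive resolutions by shared-sample count
    and the proportion relative to the higher-resolution cluster; edges with
    proportion <= ``min_proportion`` are suppressed from reports.
    ``stability`` marks, per reference-resolution cluster, the span of
    resolutions with a Jaccard-similar (>= threshold) counterpart.
    """

    assignments: dict[int, np.ndarray]
    edges: pd.DataFrame
    stability: pd.DataFrame
    reference_k: int
    jaccard_threshold: float = 0.85
    min_proportion: float = 0.1

    def reported_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["proportion"] > self.min_proportion]


def clustering_tree(
    pc_scores: np.ndarray,
    k_range: Sequence[int] = range(2, 21),
    reference_k: int = 16,
    jaccard_threshold: float = 0.85,
    max_iter: int = 10,
) -> ClusterTree:
    """Run the cut-and-consolidate pipeline at every resolution in ``k_range``.

    The Ward tree is built once on the same PC space and cut at each k; each
    cut is consolidated with k-means.  Stability of each reference-resolution
    cluster is the contiguous span of resolutions (through the reference)
    whose best-matching cluster reaches the Jaccard threshold.
    """
    ks = sorted(k_range)
    Z = linkage(pc_scores, method="ward")
    assignments: dict[int, np.ndarray] = {}
    for k in ks:
        initial = _relabel(fcluster(Z, t=k, criterion="maxclust"))
        assignments[k] = kmeans_consolidate(pc_scores, initial, max_iter).assignments.to_numpy()
    edge_rows = []
    for k_lo, k_hi in zip(ks, ks[1:]):
        lo, hi = assignments[k_lo], assignments[k_hi]
        for c_hi in np.unique(hi):
            members = set(np.flatnonzero(hi == c_hi))
            for c_lo in np.unique(lo):
                shared = len(members & set(np.flatnonzero(lo == c_lo)))
                if shared:
                    edge_rows.append(
                        (k_lo, int(c_lo), k_hi, int(c_hi), shared, shared / len(members))
                    )
    edges = pd.DataFrame(
        edge_rows,
        columns=["k_from", "cluster_from", "k_to", "cluster_to", "shared", "proportion"],
    )
    ref = reference_k if reference_k in assignments else ks[-1]
    stab_rows = []
    ref_assign = assignments[ref]
    for c in np.unique(ref_assign):
        members = set(np.flatnonzero(ref_assign == c))
        similar = {}
        for k in ks:
            best = max(
                jaccard(members, set(np.flatnonzero(assignments[k] == cc)))
                for cc in np.unique(assignments[k])
            )
            similar[k] = best >= jaccard_threshold
        lo = ref
        while lo - 1 in assignments and similar[lo - 1]:
            lo -= 1
        hi = ref
        while hi + 1 in assignments and similar[hi + 1]:
            hi += 1
        stab_rows.append((int(c), lo, hi))
    stability = pd.DataFrame(stab_rows, columns=["cluster", "stable_from_k", "stable_to_k"])
    return ClusterTree(assignments, edges, stability, ref, jaccard_threshold)


@dataclass
class Assignment:
    cluster: int
    distances: np.ndarray
    tie_set: tuple[int, ...]


def assign_new_sample(
    features: pd.Series,
    pca: PCAModel,
    model: ClusterModel,
    tol: float = 1e-9,
) -> Assignment:
    """Assign a new genome to the nearest cluster centroid in selected-PC space.

    The sample's feature vector must be complete; its recurrence features
    should be computed against the reference cohort (they may be
    underestimated when the reference alone defines recurrence — rebuild the
    index including the new sample for the alternative behaviour).  Distances
    within ``tol`` of the minimum are reported as a tie set rather than
    silently broken.
    """
    missing = [f for f in pca.loadings.index if f not in features.index or pd.isna(features[f])]
    if missing:
        raise ValueError(f"incomplete feature vector; missing {missing[:5]}...")
    score = pca.transform(features.to_frame().T)[0]
    d = np.sqrt(((model.centroids - score) ** 2).sum(axis=1))
    ties = tuple(int(i) for i in np.flatnonzero(d - d.min() <= tol))
    return Assignment(cluster=ties[0], distances=d, tie_set=ties)
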