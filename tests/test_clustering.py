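"""Scaling, PCA selection, Ward + k-means consolidation, v-tests, tree, assignment."""

import numpy as np
import pandas as pd
import pytest

from recurmut.clustering import (
    Assignment,
    assign_new_sample,
    between_cluster_variance,
    cluster_cohort,
    clustering_tree,
    fit_pca,
    hierarchical_cluster,
    jaccard,
    kmeans_consolidate,
    scale_features,
    vtest_associations,
)
from recurmut.features import FeatureMatrix


def frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, columns=[f"{prefix}{i}" for i in range(arr.shape[1])])


def two_blobs(n=30, sep=10.0, dim=3, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n, dim))
    b = rng.normal(sep, 1, (n, dim))
    return np.vstack([a, b]), np.repeat([0, 1], n)


# ------------------------------------------------------------------- scaling


def test_scaling_population_convention():
    scaled, means, scales = scale_features(frame([[1.0], [3.0]]))
    assert scaled.iloc[:, 0].tolist() == [-1.0, 1.0]  # sd with denominator N
    assert means.iloc[0] == 2.0 and scales.iloc[0] == 1.0


def test_scaling_idempotent_and_constant_column():
    rng = np.random.default_rng(1)
    X = frame(np.column_stack([rng.normal(5, 2, 50), np.full(50, 7.0)]))
    scaled, _, _ = scale_features(X)
    again, _, _ = scale_features(scaled)
    col = scaled.iloc[:, 0]
    assert np.allclose(again.iloc[:, 0], col / col.std(ddof=0))
    assert np.allclose(again.iloc[:, 0], col, atol=1e-12)
    assert (scaled.iloc[:, 1] == 0).all()


def test_scaling_rejects_single_sample():
    with pytest.raises(ValueError):
        scale_features(frame([[1.0, 2.0]]))


# ----------------------------------------------------------------------- PCA


def test_pca_collinear_data_selects_one_component():
    t = np.linspace(0, 1, 40)
    X = frame(np.column_stack([t, 2 * t, -t]))
    scaled, means, scales = scale_features(X)
    model = fit_pca(scaled, means=means, scales=scales)
    assert model.explained_variance_ratio[0] == pytest.approx(1.0)
    assert model.n_selected == 1


def test_pca_isotropic_data_selects_80pct_of_dims():
    rng = np.random.default_rng(3)
    p = 20
    X = frame(rng.normal(size=(5000, p)))
    scaled, _, _ = scale_features(X)
    model = fit_pca(scaled)
    # isotropic: cumulative ratio ~ m/p, so selection lands near ceil(0.8 p)
    assert abs(model.n_selected - int(np.ceil(0.8 * p))) <= 1


def test_pca_reconstruction_and_orthonormality():
    rng = np.random.default_rng(4)
    X = frame(rng.normal(size=(60, 8)))
    scaled, means, scales = scale_features(X)
    model = fit_pca(scaled, means=means, scales=scales)
    L = model.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-9)
    scores = model.transform(X, n_components=L.shape[1])
    assert np.allclose(scores @ L.T, scaled.to_numpy(), atol=1e-9)
    assert model.explained_variance_ratio.sum() == pytest.approx(1.0)
    # per-feature contributions to a component sum to 100%
    assert np.allclose(model.feature_contributions.sum(axis=0), 100.0)


def test_pca_sign_convention_is_deterministic():
    rng = np.random.default_rng(5)
    X = frame(rng.normal(size=(40, 5)))
    scaled, _, _ = scale_features(X)
    a, b = fit_pca(scaled), fit_pca(scaled)
    for model in (a, b):
        for col in model.loadings.columns:
            v = model.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0
    pd.testing.assert_frame_equal(a.loadings, b.loadings)


# ------------------------------------------------------------------ hierarchy


def test_ward_separates_two_blobs():
    X, truth = two_blobs()
    assign, Z = hierarchical_cluster(X, 2)
    assert len(np.unique(assign)) == 2
    assert (assign == truth).all() or (assign == 1 - truth).all()


def test_ward_k_equals_n_gives_singletons():
    X, _ = two_blobs(n=5)
    assign, _ = hierarchical_cluster(X, 10)
    assert len(np.unique(assign)) == 10


def test_ward_permutation_invariant_up_to_relabeling():
    X, _ = two_blobs(n=15, sep=6)
    rng = np.random.default_rng(9)
    perm = rng.permutation(len(X))
    a, _ = hierarchical_cluster(X, 3)
    b, _ = hierarchical_cluster(X[perm], 3)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(a[perm], b) == 1.0


def test_ward_rejects_out_of_range_k():
    X, _ = two_blobs(n=5)
    with pytest.raises(ValueError):
        hierarchical_cluster(X, 1)
    with pytest.raises(ValueError):
        hierarchical_cluster(X, 11)


# -------------------------------------------------------------- consolidation


def test_kmeans_fixed_point_unchanged():
    X, truth = two_blobs(sep=20)
    model = kmeans_consolidate(X, truth)
    assert (model.assignments.to_numpy() == truth).all()
    assert len(model.variance_history) == 1


def test_kmeans_reassigns_mislabeled_point():
    X, truth = two_blobs(n=20, sep=12)
    noisy = truth.copy()
    noisy[0] = 1  # a point from blob 0 mislabeled into cluster 1
    model = kmeans_consolidate(X, noisy)
    assert model.assignments.iloc[0] == model.assignments.iloc[1]
    assert model.between_cluster_variance >= between_cluster_variance(X, noisy)


def test_kmeans_between_variance_monotone_on_random_fixtures():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n, d, k = int(rng.integers(20, 60)), int(rng.integers(2, 6)), int(rng.integers(2, 6))
        X = rng.normal(size=(n, d)) + rng.choice([0, 3], size=(n, 1))
        init = rng.integers(0, k, size=n)
        while len(np.unique(init)) < k:
            init = rng.integers(0, k, size=n)
        model = kmeans_consolidate(X, init, max_iter=10)
        diffs = np.diff(model.variance_history)
        assert (diffs >= -1e-9).all()
        # total variance is conserved: between <= total always
        assert model.between_cluster_variance <= X.var(axis=0, ddof=0).sum() + 1e-9


def test_kmeans_centroids_are_member_means():
    X, truth = two_blobs()
    model = kmeans_consolidate(X, truth)
    for c in range(model.k):
        members = X[model.assignments.to_numpy() == c]
        assert np.allclose(model.centroids[c], members.mean(axis=0))


# -------------------------------------------------------------------- v-test


def test_vtest_zero_when_cluster_mean_equals_grand_mean():
    X = frame(np.array([[1.0, 5.0], [3.0, 5.0], [1.0, 5.0], [3.0, 5.0]]))
    res = vtest_associations(X, np.array([0, 0, 1, 1]))
    f0 = res[res.feature == "f0"]
    assert np.allclose(f0.v_statistic, 0.0)
    assert np.allclose(f0.p_raw, 1.0)


def test_vtest_antisymmetric_for_balanced_two_clusters():
    rng = np.random.default_rng(21)
    X = frame(rng.normal(size=(40, 3)))
    labels = np.repeat([0, 1], 20)
    res = vtest_associations(X, labels).set_index(["cluster", "feature"])
    for f in X.columns:
        assert res.loc[(0, f), "v_statistic"] == pytest.approx(
            -res.loc[(1, f), "v_statistic"])


def test_vtest_detects_planted_shift_and_controls_others():
    rng = np.random.default_rng(22)
    n = 60
    X = rng.normal(size=(n, 6))
    labels = np.repeat([0, 1, 2], n // 3)
    X[labels == 1, 2] += 3.0  # +3 SD shift of feature f2 in cluster 1
    res = vtest_associations(frame(X), labels)
    hit = res[(res.cluster == 1) & (res.feature == "f2")].iloc[0]
    assert hit.direction == "positive" and hit.p_adjusted <= 0.05
    others = res[~((res.feature == "f2"))]
    assert (others.direction == "none").mean() > 0.9


def test_vtest_rejects_single_cluster():
    with pytest.raises(ValueError):
        vtest_associations(frame(np.ones((4, 2))), np.zeros(4, dtype=int))


# ---------------------------------------------------------------------- tree


def test_jaccard_identities():
    assert jaccard({1, 2}, {1, 2}) == 1.0
    assert jaccard({1}, {2}) == 0.0


def test_clustering_tree_stable_blob_and_edges():
    rng = np.random.default_rng(31)
    # three groups: one tight isolated blob and two close ones that merge first
    X = np.vstack([
        rng.normal(0, 0.5, (20, 2)),
        rng.normal([30, 0], 0.5, (20, 2)),
        rng.normal([30, 6], 0.5, (20, 2)),
    ])
    tree = clustering_tree(X, k_range=range(2, 6), reference_k=3)
    # the isolated blob persists across every resolution with Jaccard 1
    members = set(range(20))
    for k, assign in tree.assignments.items():
        best = max(
            jaccard(members, set(np.flatnonzero(assign == c)))
            for c in np.unique(assign)
        )
        assert best == 1.0
    row = tree.stability.set_index("cluster")
    blob_cluster = tree.assignments[3][0]
    assert row.loc[blob_cluster, "stable_from_k"] == 2
    assert row.loc[blob_cluster, "stable_to_k"] == 5
    # reported edges hide flows with proportion <= 0.1
    assert (tree.reported_edges()["proportion"] > 0.1).all()
    # shared counts never exceed either endpoint's size
    for e in tree.edges.itertuples():
        assert e.shared <= (tree.assignments[e.k_to] == e.cluster_to).sum()
        assert e.shared <= (tree.assignments[e.k_from] == e.cluster_from).sum()


# ---------------------------------------------------------------- assignment


def _toy_model(sep=8.0):
    X, truth = two_blobs(n=25, sep=sep, dim=4, seed=40)
    fm = FeatureMatrix(frame(X))
    pca, model = cluster_cohort(fm, k=2)
    return X, fm, pca, model


def test_assign_centroid_maps_to_own_cluster():
    X, fm, pca, model = _toy_model()
    centroid_scores = model.centroids
    # invert: build a feature vector whose projection is exactly the centroid
    for c in range(model.k):
        members = fm.data[model.assignments.to_numpy() == c]
        mean_features = members.mean(axis=0)
        a = assign_new_sample(mean_features, pca, model)
        assert a.cluster == c
        assert a.distances[c] == pytest.approx(min(a.distances))


def test_assign_reports_tie_set():
    X = np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 0.0], [4.0, 1.0]])
    fm = FeatureMatrix(frame(X))
    pca, model = cluster_cohort(fm, k=2)
    midpoint = fm.data.mean(axis=0)
    a = assign_new_sample(midpoint, pca, model)
    assert len(a.tie_set) == 2


def test_assign_rejects_incomplete_features():
    _, fm, pca, model = _toy_model()
    broken = fm.data.iloc[0].drop("f0")
    with pytest.raises(ValueError):
        assign_new_sample(broken, pca, model)


def test_pipeline_invariant_to_sample_order(small_cohort):
    from recurmut.features import assemble_feature_matrix
    from sklearn.metrics import adjusted_rand_score

    _, norm = small_cohort
    ids = list(dict.fromkeys(norm["sample_id"]))
    fm1 = assemble_feature_matrix(norm, sample_ids=ids)
    fm2 = assemble_feature_matrix(norm, sample_ids=ids[::-1])
    _, m1 = cluster_cohort(fm1, k=4)
    _, m2 = cluster_cohort(fm2, k=4)
    joined = pd.concat([m1.assignments.rename("a"), m2.assignments.rename("b")], axis=1)
    assert adjusted_rand_score(joined.a, joined.b) == 1.0
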