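"""kNN-Jaccard graph construction, Louvain communities, embeddings."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

import lungplex as lp
from lungplex.clustering import (
    DEFAULT_K,
    PhenoGraphClusterer,
    build_knn_jaccard_graph,
    knn_adjacency,
    louvain_communities,
    modularity,
    replicate_entropy,
)


def _blobs(n_per=200, dim=10, sd=0.03, seed=0):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, 1, (3, dim))
    X = np.vstack([rng.normal(c, sd, (n_per, dim)) for c in centers])
    return X, np.repeat([0, 1, 2], n_per)


def test_knn_outdegree_before_symmetrization():
    X = np.array([[0.0], [1.0], [3.0]])
    A = knn_adjacency(X, k=1)
    assert (A.sum(axis=1) == 1).all()


def test_k_exceeding_sample_size_rejected():
    with pytest.raises(ValueError, match="k exceeds sample size"):
        build_knn_jaccard_graph(np.zeros((10, 3)), k=10)


def test_identical_neighbor_sets_weight_one():
    # duplicated point inside a far-away cloud: same neighbourhood -> w = 1
    rng = np.random.default_rng(3)
    X = np.vstack([[0, 0], [0, 0], rng.normal(5, 1, (10, 2))])
    W = build_knn_jaccard_graph(X, k=3)
    assert W[0, 1] == 1.0


def test_jaccard_weights_match_bruteforce_sets():
    rng = np.random.default_rng(11)
    X = rng.normal(0, 1, (50, 5))
    k = 6
    D = cdist(X, X)
    sets = []
    for i in range(50):
        order = np.argsort(D[i], kind="stable")
        order = order[order != i][:k]
        sets.append(set(order.tolist()) | {i})
    W = build_knn_jaccard_graph(X, k).toarray()
    for i in range(50):
        for j in range(50):
            linked = i != j and (j in sets[i] or i in sets[j])
            expect = (
                len(sets[i] & sets[j]) / len(sets[i] | sets[j]) if linked else 0.0
            )
            assert W[i, j] == pytest.approx(expect, abs=1e-12)


class TestLouvain:
    def test_two_cliques_resolved(self):
        n = 40
        A = np.zeros((n, n))
        A[:20, :20] = 1
        A[20:, 20:] = 1
        np.fill_diagonal(A, 0)
        A[0, 20] = A[20, 0] = 1
        labels = louvain_communities(A, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]
        # beats the all-singletons partition
        assert modularity(A, labels) >= modularity(A, np.arange(n))

    def test_single_node_and_empty(self):
        assert louvain_communities(np.zeros((1, 1)), seed=0).tolist() == [0]
        assert louvain_communities(np.zeros((0, 0)), seed=0).size == 0

    def test_three_blobs_exact_recovery(self):
        X, y = _blobs()
        labels = louvain_communities(build_knn_jaccard_graph(X, 30), seed=1)
        assert len(set(labels)) == 3
        assert adjusted_rand_score(y, labels) == 1.0

    def test_deterministic_given_seed(self):
        X, _ = _blobs(seed=5)
        W = build_knn_jaccard_graph(X, 30)
        l1 = louvain_communities(W, seed=7)
        l2 = louvain_communities(W, seed=7)
        assert np.array_equal(l1, l2)


def test_row_permutation_changes_nothing_but_order():
    X, _ = _blobs(n_per=100, seed=2)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(X))
    base = PhenoGraphClusterer(k=30, seed=4).fit_predict(X)
    shuffled = PhenoGraphClusterer(k=30, seed=4).fit_predict(X[perm])
    assert adjusted_rand_score(base[perm], shuffled) == 1.0


class TestEstimatorConventions:
    def test_params_roundtrip(self):
        est = PhenoGraphClusterer(k=12, seed=3)
        assert est.get_params() == {"k": 12, "seed": 3}
        est.set_params(k=8)
        assert est.k == 8

    def test_fitted_attributes(self):
        X, _ = _blobs(n_per=50, seed=1)
        est = PhenoGraphClusterer(k=10, seed=0).fit(X)
        assert est.labels_.shape == (len(X),)
        assert est.cluster_sizes_.sum() == len(X)
        assert est.n_clusters_ == len(est.cluster_sizes_)
        assert est.graph_.shape == (len(X), len(X))

    def test_default_k_is_recorded(self):
        X, _ = _blobs(n_per=50, seed=1)
        est = PhenoGraphClusterer().fit(X)
        res = est.result(X)
        assert est.k == DEFAULT_K == res.k_neighbors == 30


class TestEmbeddings:
    def test_degenerate_identical_rows_finite(self):
        e = lp.embed(np.ones((10, 5)), "tsne", seed=0)
        assert e.shape == (10, 2) and np.isfinite(e).all()

    def test_same_seed_reproduces(self):
        X, _ = _blobs(n_per=40, seed=3)
        a = lp.embed(X, "tsne", seed=5)
        b = lp.embed(X, "tsne", seed=5)
        assert np.array_equal(a, b)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown embedding method"):
            lp.embed(np.ones((10, 2)), "pca", seed=0)

    def test_blob_structure_preserved(self):
        X, y = _blobs(n_per=100, seed=4)
        e = lp.embed(X, "tsne", seed=0)
        assert silhouette_score(e, y) > 0.5

    def test_umap_smoke(self):
        X, y = _blobs(n_per=40, seed=6)
        e = lp.embed(X, "umap", seed=1)
        assert e.shape == (120, 2) and np.isfinite(e).all()


class TestClusterMeans:
    def test_identical_cells_recover_profile(self):
        X = np.tile([0.2, 0.7, 0.1], (12, 1))
        means = lp.cluster_mean_matrix(X, np.zeros(12, dtype=int))
        np.testing.assert_allclose(means.iloc[0].to_numpy(), [0.2, 0.7, 0.1])

    def test_matches_bruteforce_groupby(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (40, 4))
        labels = rng.integers(0, 3, 40)
        means = lp.cluster_mean_matrix(X, labels)
        for c in np.unique(labels):
            np.testing.assert_allclose(
                means.loc[c].to_numpy(), X[labels == c].mean(axis=0)
            )

    def test_empty_cluster_excluded_with_warning(self):
        X = np.ones((4, 2))
        labels = np.array([0, 0, 2, 2])  # cluster 1 empty
        with pytest.warns(UserWarning, match="zero cells"):
            means = lp.cluster_mean_matrix(X, labels)
        assert list(means.index) == [0, 2]

    def test_marker_contrast_in_pure_cluster(self, tabular_section):
        gt, table = tabular_section
        at1 = table[gt.cells["true_type"].to_numpy() == "AT1"]
        means = lp.cluster_mean_matrix(at1, np.zeros(len(at1), dtype=int))
        assert means.loc[0, "AQP5"] > means.loc[0, "CD3"]


def test_replicate_mixing_no_batch_effect(panel):
    """Clusters on pooled identical-parameter replicates contain cells of both."""
    from lungplex import synthgen

    tables = []
    for i, seed in enumerate([21, 22]):
        params = synthgen.normal_core_params(
            seed=seed, n_cells=900, field_shape=(900, 900)
        )
        gt = synthgen.generate_ground_truth(params, panel=panel)
        tables.append(synthgen.cell_table_from_truth(gt, panel, sample_id=f"rep{i}"))
    combined = pd.concat(tables, ignore_index=True)
    X = lp.scaled_matrix(combined, lp.classification_markers(panel))
    labels = PhenoGraphClusterer(k=30, seed=2).fit_predict(X)
    ent = replicate_entropy(labels, combined["sample_id"].to_numpy())
    sizes = pd.Series(labels).value_counts()
    for c, size in sizes.items():
        if size >= 50:
            assert ent[c] > 0.0
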