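"""K-means with metric-matched centroid rules."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans

import ecgist as e
from ecgist.clustering import ClusterConfig, _distance_matrix


def naive_distance(x, c, metric):
    """Independent formula oracle, written directly from the definitions."""
    x, c = np.asarray(x, float), np.asarray(c, float)
    if metric == "l2":
        return float(np.sum((x - c) ** 2))
    if metric == "l1":
        return float(np.sum(np.abs(x - c)))
    if metric == "cosine":
        return 1.0 - float(x @ c) / (np.sqrt(x @ x) * np.sqrt(c @ c))
    xc, cc = x - x.mean(), c - c.mean()
    return 1.0 - float(xc @ cc) / (np.linalg.norm(xc) * np.linalg.norm(cc))


vectors = st.lists(st.floats(-10, 10), min_size=4, max_size=12)


class TestDistance:
    def test_cosine_identities(self):
        x = np.array([1.0, 2.0, -1.0])
        assert e.distance(x, x, "cosine") == pytest.approx(0.0, abs=1e-12)
        assert e.distance(x, -x, "cosine") == pytest.approx(2.0)
        assert e.distance(np.array([1.0, 0.0, 0.0]),
                          np.array([0.0, 1.0, 0.0]), "cosine") == 1.0

    def test_correlation_shift_invariant(self):
        x = np.array([0.5, 1.5, -2.0, 3.0])
        assert e.distance(x, x + 7.0, "correlation") == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_inputs_fall_back_to_one(self):
        zero = np.zeros(4)
        flat = np.full(4, 2.0)
        x = np.array([1.0, -1.0, 2.0, 0.0])
        assert e.distance(zero, x, "cosine") == 1.0
        assert e.distance(flat, x, "correlation") == 1.0

    @settings(max_examples=40, deadline=None)
    @given(vectors, st.sampled_from(["l1", "l2", "cosine", "correlation"]),
           st.integers(0, 10**6))
    def test_matches_direct_formula(self, base, metric, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(base)
        c = rng.normal(size=x.size)
        if metric in ("cosine", "correlation"):
            x = x + rng.normal(size=x.size) * 0.1  # avoid exact degeneracy
            if np.allclose(x, x.mean()) or np.allclose(c, c.mean()):
                return
        assert e.distance(x, c, metric) == pytest.approx(
            naive_distance(x, c, metric), abs=1e-9)

    def test_vectorized_matrix_agrees_with_scalar(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 9))
        C = rng.normal(size=(3, 9))
        for metric in ("l1", "l2", "cosine", "correlation"):
            mat = _distance_matrix(X, C, metric)
            for i in range(7):
                for k in range(3):
                    assert mat[i, k] == pytest.approx(
                        e.distance(X[i], C[k], metric), abs=1e-9)


class TestUpdateCentroids:
    def test_single_cluster_l2_is_global_mean(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        C = e.update_centroids(X, np.zeros(20, dtype=int), "l2", K=1)
        np.testing.assert_allclose(C[0], X.mean(axis=0))

    def test_l1_centroid_is_median(self):
        X = np.array([[1.0], [3.0], [100.0]])
        C = e.update_centroids(X, np.zeros(3, dtype=int), "l1", K=1)
        assert C[0, 0] == 3.0

    def test_random_partition_matches_direct_recomputation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6))
        labels = rng.integers(0, 3, size=30)
        for metric in ("l1", "l2", "cosine", "correlation"):
            C = e.update_centroids(X, labels, metric, K=3)
            for k in range(3):
                members = X[labels == k]
                if metric == "l2":
                    expected = members.mean(axis=0)
                elif metric == "l1":
                    expected = np.median(members, axis=0)
                elif metric == "cosine":
                    u = members / np.linalg.norm(members, axis=1, keepdims=True)
                    expected = u.mean(axis=0)
                else:
                    z = members - members.mean(axis=1, keepdims=True)
                    z = z / np.linalg.norm(z, axis=1, keepdims=True)
                    expected = z.mean(axis=0)
                np.testing.assert_allclose(C[k], expected, atol=1e-12)

    def test_empty_cluster_reseeded(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [5.0, 5.0]])
        labels = np.array([0, 0, 0])
        C = e.update_centroids(X, labels, "l2", K=2)
        assert np.isfinite(C).all()
        assert not np.allclose(C[1], 0.0)  # re-seeded from the data


class TestKmeansFit:
    def test_k_equals_m_gives_zero_objective(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        fit = e.kmeans_fit(X, ClusterConfig(K=6, metric="l2", n_restarts=3))
        assert fit.objective_trace[-1] == pytest.approx(0.0, abs=1e-18)

    def test_two_blobs_recovered_exactly(self):
        """Brute-force optimal 2-partition on 10 points: two well-separated
        Gaussian blobs must be split exactly."""
        rng = np.random.default_rng(11)
        X = np.vstack([rng.normal(0, 0.1, size=(5, 3)),
                       rng.normal(8, 0.1, size=(5, 3))])
        fit = e.kmeans_fit(X, ClusterConfig(K=2, metric="l2", rng_seed=0))
        labels = fit.labels
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_matches_sklearn_on_l2(self):
        """Independent implementation oracle: same objective as sklearn
        KMeans on an easy dataset."""
        rng = np.random.default_rng(21)
        X = np.vstack([rng.normal(c, 0.3, size=(15, 4)) for c in (0, 5, 10)])
        ours = e.kmeans_fit(X, ClusterConfig(K=3, metric="l2", rng_seed=1))
        ref = KMeans(n_clusters=3, n_init=10, random_state=1).fit(X)
        assert ours.objective_trace[-1] == pytest.approx(ref.inertia_, rel=1e-6)

    @pytest.mark.parametrize("metric", ["l1", "l2", "cosine", "correlation"])
    def test_objective_non_increasing(self, metric):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(40, 8))
        fit = e.kmeans_fit(X, ClusterConfig(K=3, metric=metric, rng_seed=2))
        trace = fit.objective_trace
        assert (np.diff(trace) <= 1e-9).all(), trace

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(30, 5))
        f1 = e.kmeans_fit(X, ClusterConfig(K=3, rng_seed=9))
        f2 = e.kmeans_fit(X, ClusterConfig(K=3, rng_seed=9))
        np.testing.assert_array_equal(f1.labels, f2.labels)

    def test_k_larger_than_data_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            e.kmeans_fit(np.zeros((3, 2)), ClusterConfig(K=4))

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10**6),
           st.sampled_from(["l1", "l2", "cosine", "correlation"]))
    def test_distances_bounded(self, seed, metric):
        """Cosine/correlation distances lie in [0, 2]; L1/L2 are >= 0."""
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 6))
        C = rng.normal(size=(2, 6))
        d = _distance_matrix(X, C, metric)
        assert (d >= -1e-12).all()
        if metric in ("cosine", "correlation"):
            assert (d <= 2.0 + 1e-12).all()


class TestClusterMap:
    def test_all_same_label_single_component(self, ico_mesh):
        fit = e.ClusterResult(np.zeros((1, 3)), np.zeros(12, dtype=int),
                              np.array([0.0]), "l2")
        labels, components = e.cluster_map(fit, ico_mesh)
        assert components == {0: 1}

    def test_planted_regions_one_component_each(self, small_study):
        """Planted 4-region sphere: each recovered cluster is one
        edge-connected patch (BFS component oracle via networkx)."""
        import networkx as nx

        mesh, layout, cfg, rec, ann = small_study
        clean, ann2 = e.preprocess_recording(rec, annotation=ann)
        X = np.stack([
            e.extract_beat_window(clean.signals[i], ann2.fiducials[i][0],
                                  cfg.fs)[0]
            for i in range(clean.node_count)
        ])
        fit = e.kmeans_fit(X, ClusterConfig(K=4, metric="cosine", rng_seed=0))
        labels, components = e.cluster_map(fit, mesh)
        g = nx.Graph()
        for tri in mesh.triangles:
            g.add_edges_from([(tri[0], tri[1]), (tri[1], tri[2]),
                              (tri[0], tri[2])])
        for k, n_comp in components.items():
            nodes = np.flatnonzero(labels == k)
            expected = nx.number_connected_components(g.subgraph(nodes))
            assert n_comp == expected
            assert n_comp == 1

    def test_labels_reindexed_by_size(self):
        mesh = e.SurfaceMesh(np.eye(3), [[0, 1, 2]])
        fit = e.ClusterResult(np.zeros((2, 2)), np.array([1, 1, 0]),
                              np.array([0.0]), "l2")
        labels, _ = e.cluster_map(fit, mesh)
        assert labels.tolist() == [0, 0, 1]

    def test_empty_mesh_empty_map(self):
        mesh = e.SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        fit = e.ClusterResult(np.zeros((1, 2)), np.array([], dtype=int),
                              np.array([0.0]), "l2")
        labels, components = e.cluster_map(fit, mesh)
        assert labels.size == 0 and components == {}
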