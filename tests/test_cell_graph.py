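import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ladgcn.cell_graph import adjacency_to_mtx, build_graph, load_graph, normalize_adjacency, save_graph


def brute_force_edges(points, k, d):
    """Independent O(m^2) enumeration of the KNN + distance-threshold rule."""
    m = len(points)
    edges = set()
    for i in range(m):
        dists = []
        for j in range(m):
            if j == i:
                continue
            dij = math.hypot(points[i][0] - points[j][0], points[i][1] - points[j][1])
            dists.append((dij, j))
        dists.sort()
        for dij, j in dists[:k]:
            if dij < d:
                edges.add((i, j))
    return edges


class TestBuildGraph:
    def test_three_point_knn_example(self):
        cents = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 3.0]])  # collinear, gaps 1 and 2
        g = build_graph(cents, k=1, d=10.0)
        assert set(g.directed_edges) == {(0, 1), (1, 0), (2, 1)}
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert np.array_equal(g.a, expected)

    def test_distance_threshold_prunes_far_neighbour(self):
        cents = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 3.0]])
        g = build_graph(cents, k=1, d=1.5)
        assert set(g.directed_edges) == {(0, 1), (1, 0)}
        assert g.a[1, 2] == 0

    def test_single_node_graph(self):
        g = build_graph(np.array([[5.0, 5.0]]))
        assert g.directed_edges == []
        assert np.array_equal(g.a, [[0.0]])
        assert np.array_equal(g.a_norm, [[1.0]])

    def test_knn_tie_at_kth_neighbour_broken_by_lower_index(self):
        # node 0 at the origin; nodes 1 and 2 both at distance 1
        cents = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        g = build_graph(cents, k=1, d=10.0)
        assert (0, 1) in g.directed_edges and (0, 2) not in g.directed_edges

    @given(
        st.integers(1, 50),
        st.integers(1, 8),
        st.floats(5.0, 80.0),
        st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, m, k, d, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 100, (m, 2))
        g = build_graph(pts, k=k, d=d)
        assert set(g.directed_edges) == brute_force_edges(pts.tolist(), k, d)

    def test_enlarging_k_or_d_never_removes_edges(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 100, (30, 2))
        base = set(build_graph(pts, k=3, d=30.0).directed_edges)
        assert base <= set(build_graph(pts, k=5, d=30.0).directed_edges)
        assert base <= set(build_graph(pts, k=3, d=60.0).directed_edges)

    def test_directed_out_degree_bounded_by_k(self):
        # symmetric degree can exceed 2K at hub nodes (a point may be among
        # the K nearest of many others), but out-degree never exceeds K
        rng = np.random.default_rng(6)
        for k in (1, 3, 5):
            pts = rng.uniform(0, 60, (40, 2))
            g = build_graph(pts, k=k, d=100.0)
            out_deg = np.bincount([i for i, _ in g.directed_edges], minlength=40)
            assert out_deg.max() <= k


class TestNormalizeAdjacency:
    def test_two_connected_nodes(self):
        a_norm = normalize_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(a_norm, [[0.5, 0.5], [0.5, 0.5]])

    def test_edgeless_graph_normalizes_to_identity(self):
        assert np.allclose(normalize_adjacency(np.zeros((4, 4))), np.eye(4))

    def test_complete_triangle(self):
        a_norm = normalize_adjacency(np.ones((3, 3)) - np.eye(3))
        assert np.allclose(a_norm, 1.0 / 3.0)

    def test_diagonal_entries_are_inverse_degree_plus_one(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 100, (25, 2))
        g = build_graph(pts, k=4, d=50.0)
        deg = g.a.sum(axis=1)
        assert np.allclose(np.diag(g.a_norm), 1.0 / (deg + 1.0))

    def test_leading_eigenvalue_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            pts = rng.uniform(0, 100, (rng.integers(2, 30), 2))
            g = build_graph(pts, k=int(rng.integers(1, 6)), d=float(rng.uniform(20, 80)))
            assert np.linalg.eigvalsh(g.a_norm).max() == pytest.approx(1.0, abs=1e-9)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_adjacency(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestGraphIO:
    def test_json_roundtrip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(1)
        g = build_graph(rng.uniform(0, 100, (12, 2)), rng.normal(size=(12, 5)), k=3, d=40.0)
        path = tmp_path / "graph.json"
        save_graph(g, path)
        back = load_graph(path)
        assert np.allclose(back.centroids, g.centroids, atol=1e-12)
        assert np.allclose(back.node_features, g.node_features, atol=1e-12)
        assert back.directed_edges == g.directed_edges
        assert np.array_equal(back.a, g.a)
        assert np.allclose(back.a_norm, g.a_norm, atol=1e-12)
        assert (back.k, back.d) == (g.k, g.d)

    def test_tampered_asymmetric_file_rejected(self, tmp_path):
        import json

        g = build_graph(np.array([[0.0, 0.0], [0.0, 1.0]]), k=1, d=10.0)
        path = tmp_path / "graph.json"
        save_graph(g, path)
        payload = json.loads(path.read_text())
        payload["undirected_edges"] = []  # no longer the symmetrization
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError):
            load_graph(path)

    def test_empty_graph_roundtrip(self, tmp_path):
        g = build_graph(np.zeros((0, 2)), np.zeros((0, 3)), k=2, d=10.0)
        path = tmp_path / "empty.json"
        save_graph(g, path)
        back = load_graph(path)
        assert back.n_nodes == 0
        assert back.directed_edges == []

    def test_mtx_export_readable_by_scipy(self, tmp_path):
        from scipy.io import mmread

        g = build_graph(np.array([[0.0, 0.0], [0.0, 1.0], [5.0, 5.0]]), k=1, d=3.0)
        path = tmp_path / "adj.mtx"
        adjacency_to_mtx(g, path)
        assert np.array_equal(mmread(path).toarray(), g.a)
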