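"""Cell-graph construction from nucleus centroids.

Nodes are nucleus centroids with attached feature vectors.  A directed
edge (i, j) exists iff j is among i's K nearest neighbours (Euclidean)
AND D(i, j) < d; the undirected adjacency A is the OR-symmetrization of
those directed edges.  The GCN consumes the self-looped symmetrically
normalized adjacency A_norm = D~^{-1/2} (A + I) D~^{-1/2}.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.io import mmwrite
from scipy.sparse import coo_matrix
from scipy.spatial.distance import cdist

__all__ = ["CellGraph", "build_graph", "normalize_adjacency", "save_graph", "load_graph", "adjacency_to_mtx"]

DEFAULT_K = 5
DEFAULT_D = 50.0  # px; edge distance cutoff at the synthetic tile scale


@dataclasses.dataclass
class CellGraph:
    centroids: np.ndarray  # m x 2 (row, col) px
    node_features: np.ndarray  # m x f
    directed_edges: list[tuple[int, int]]
    a: np.ndarray  # m x m binary symmetric, zero diagonal
    a_norm: np.ndarray  # m x m normalized self-looped adjacency
    k: int
    d: float

    @property
    def n_nodes(self) -> int:
        return int(self.centroids.shape[0])


def build_graph(
    centroids: np.ndarray,
    node_features: np.ndarray | None = None,
    k: int = DEFAULT_K,
    d: float = DEFAULT_D,
) -> CellGraph:
    """KNN-with-distance-threshold cell graph.

    Neighbour ranking excludes the node itself; ties at the K-th
    neighbour are broken by lower node index (stable sort); the distance
    test is strict (D < d).  Isolated nodes (and m = 1 graphs) are valid.
    """
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 2)
    m = centroids.shape[0]
    if node_features is None:
        node_features = np.zeros((m, 0))
    node_features = np.asarray(node_features, dtype=np.float64)
    if node_features.shape[0] != m:
        raise ValueError("node_features rows must match number of centroids")
    if k < 1 or d <= 0:
        raise ValueError("require K >= 1 and d > 0")
    directed: list[tuple[int, int]] = []
    a = np.zeros((m, m), dtype=np.float64)
    if m > 1:
        dist = cdist(centroids, centroids)
        np.fill_diagonal(dist, np.inf)
        order = np.argsort(dist, axis=1, kind="stable")  # stable => lower-index tie-break
        for i in range(m):
            for j in order[i, : min(k, m - 1)]:
                if dist[i, j] < d:
                    directed.append((i, int(j)))
                    a[i, j] = 1.0
                    a[j, i] = 1.0
    return CellGraph(
        centroids=centroids,
        node_features=node_features,
        directed_edges=directed,
        a=a,
        a_norm=normalize_adjacency(a),
        k=int(k),
        d=float(d),
    )


def normalize_adjacency(a: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalization D~^{-1/2} (A + I) D~^{-1/2}."""
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if a.size and (not np.allclose(a, a.T) or np.any(np.diag(a) != 0)):
        raise ValueError("adjacency must be symmetric with zero diagonal")
    a_tilde = a + np.eye(a.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    return d_inv_sqrt[:, None] * a_tilde * d_inv_sqrt[None, :]


def save_graph(graph: CellGraph, path: str | Path) -> None:
    """Lossless JSON serialization of centroids, features, edges, params."""
    undirected = sorted({(min(i, j), max(i, j)) for i, j in graph.directed_edges})
    payload = {
        "centroids": graph.centroids.tolist(),
        "node_features": graph.node_features.tolist(),
        "directed_edges": [[int(i), int(j)] for i, j in graph.directed_edges],
        "undirected_edges": [[int(i), int(j)] for i, j in undirected],
        "K": graph.k,
        "d": graph.d,
    }
    Path(path).write_text(json.dumps(payload))


def load_graph(path: str | Path) -> CellGraph:
    """Load a serialized graph, enforcing the symmetric-adjacency invariant."""
    payload = json.loads(Path(path).read_text())
    centroids = np.asarray(payload["centroids"], dtype=np.float64).reshape(-1, 2)
    m = centroids.shape[0]
    if m == 0:
        features = np.zeros((0, 0))
    else:
        features = np.asarray(payload["node_features"], dtype=np.float64).reshape(m, -1)
    directed = [(int(i), int(j)) for i, j in payload["directed_edges"]]
    undirected = {(min(i, j), max(i, j)) for i, j in payload["undirected_edges"]}
    if {(min(i, j), max(i, j)) for i, j in directed} != undirected:
        raise ValueError("stored undirected edges are not the symmetrization of the directed edges")
    a = np.zeros((m, m), dtype=np.float64)
    for i, j in undirected:
        if i == j or i >= m or j >= m:
            raise ValueError("malformed edge list")
        a[i, j] = a[j, i] = 1.0
    return CellGraph(
        centroids=centroids,
        node_features=features,
        directed_edges=directed,
        a=a,
        a_norm=normalize_adjacency(a),
        k=int(payload["K"]),
        d=float(payload["d"]),
    )


def adjacency_to_mtx(graph: CellGraph, path: str | Path) -> None:
    """Export the symmetric binary adjacency as a MatrixMarket sparse file."""
    mmwrite(str(path), coo_matrix(graph.a))
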