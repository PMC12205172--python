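"""Manifold approximation: k-NN graphs, geodesic distances, variational copies.

Each modality is treated as a point cloud on a low-dimensional manifold.
The manifold is approximated Isomap-style: a weighted k-nearest-neighbor
graph is built on the feature matrix and all-pairs shortest path lengths on
that graph stand in for geodesic distances.  Self-alignment later perturbs
the modality ("variational replicates") to break the trivial identity
correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ModalityData",
    "NeighborGraph",
    "GeodesicMatrix",
    "VariationalReplicate",
    "build_knn_graph",
    "geodesic_distances",
    "geodesics_from_points",
    "make_variational",
]


@dataclass
class ModalityData:
    """A cells x features matrix with optional cell identifiers and labels.

    Parameters
    ----------
    matrix
        Dense ``(n_cells, n_features)`` real matrix.  Arbitrary units.
    cell_ids
        Optional list of cell identifiers, one per row.
    labels
        Optional per-cell categorical labels (e.g. branch or cell type).
    """

    matrix: np.ndarray
    cell_ids: list[str] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("modality matrix must be 2-D (cells x features)")
        n, p = self.matrix.shape
        if n < 3:
            raise ValueError(f"need at least 3 cells, got {n}")
        if p < 1:
            raise ValueError("need at least 1 feature")
        if not np.isfinite(self.matrix).all():
            bad = np.argwhere(~np.isfinite(self.matrix))
            i, j = bad[0]
            raise ValueError(
                f"non-finite value at cell {i}, feature {j} "
                f"({len(bad)} non-finite entries total)"
            )
        if self.cell_ids is not None and len(self.cell_ids) != n:
            raise ValueError("cell_ids length must equal number of cells")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length must equal number of cells")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class NeighborGraph:
    """Undirected weighted k-NN graph over cells.

    ``edges`` holds one ``(i, j, weight)`` triple per undirected edge with
    ``i < j``; ``k_used`` is the neighbor count that actually produced a
    connected graph (it may exceed the requested ``k``).
    """

    n_nodes: int
    edges: list[tuple[int, int, float]]
    k_used: int

    def to_sparse(self) -> csr_matrix:
        """Symmetric CSR adjacency with edge weights."""
        if not self.edges:
            return csr_matrix((self.n_nodes, self.n_nodes))
        ii, jj, ww = zip(*self.edges)
        ii, jj, ww = np.asarray(ii), np.asarray(jj), np.asarray(ww, dtype=float)
        adj = coo_matrix(
            (np.concatenate([ww, ww]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return adj.tocsr()


@dataclass
class GeodesicMatrix:
    """Symmetric matrix of graph-shortest-path geodesic approximations."""

    dist: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dist, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("geodesic matrix must be square")
        if not np.isfinite(d).all():
            raise ValueError("geodesic matrix contains non-finite entries")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("geodesic matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("geodesic matrix must have a zero diagonal")
        if (d < 0).any():
            raise ValueError("geodesic distances must be nonnegative")
        self.dist = d

    @property
    def n(self) -> int:
        return self.dist.shape[0]


@dataclass
class VariationalReplicate:
    """A noise-perturbed copy of a modality and its re-built geodesics."""

    data: ModalityData
    geodesic: GeodesicMatrix
    noise_sd: float
    k_neighbors: int
    seed: int
    k_used: int = field(default=0)


def build_knn_graph(
    data: ModalityData, k: int, metric: str = "euclidean"
) -> NeighborGraph:
    """Build the union-symmetrized weighted k-NN graph of cells.

    An undirected edge ``(i, j)`` exists iff ``j`` is among the ``k``
    nearest neighbors of ``i`` or vice versa; its weight is the feature
    distance.  If the resulting graph is disconnected, ``k`` is incremented
    until it is connected and ``k_used`` records the final value.
    """
    n = data.n_cells
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_cells, got k={k}, n={n}")

    k_used = k
    while True:
        nn = NearestNeighbors(n_neighbors=k_used + 1, metric=metric)
        nn.fit(data.matrix)
        dists, idx = nn.kneighbors(data.matrix)
        edge_w: dict[tuple[int, int], float] = {}
        zero_weight = False
        for i in range(n):
            for d, j in zip(dists[i], idx[i]):
                if j == i:
                    continue
                w = float(d)
                if w <= 0.0:
                    zero_weight = True
                    w = np.finfo(float).tiny
                key = (i, int(j)) if i < j else (int(j), i)
                edge_w[key] = min(edge_w.get(key, np.inf), w)
        if zero_weight:
            warnings.warn(
                "duplicate cells produced zero-weight edges; "
                "replaced with machine epsilon",
                stacklevel=2,
            )
        graph = NeighborGraph(
            n_nodes=n,
            edges=[(i, j, w) for (i, j), w in sorted(edge_w.items())],
            k_used=k_used,
        )
        n_comp, _ = connected_components(graph.to_sparse(), directed=False)
        if n_comp == 1:
            return graph
        if k_used + 1 >= n:  # complete graph is always connected
            return graph
        k_used += 1


def geodesic_distances(graph: NeighborGraph) -> GeodesicMatrix:
    """All-pairs shortest-path lengths on the neighbor graph (Dijkstra)."""
    adj = graph.to_sparse()
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"graph has {n_comp} connected components (sizes {sizes.tolist()}); "
            "geodesic distances are undefined"
        )
    dist = shortest_path(adj, method="D", directed=False)
    dist = 0.5 * (dist + dist.T)  # numerical symmetry
    np.fill_diagonal(dist, 0.0)
    return GeodesicMatrix(dist)


def geodesics_from_points(
    data: ModalityData, k: int, metric: str = "euclidean"
) -> tuple[GeodesicMatrix, int]:
    """Convenience: k-NN graph + geodesics; returns (matrix, k_used)."""
    graph = build_knn_graph(data, k, metric=metric)
    return geodesic_distances(graph), graph.k_used


def make_variational(
    data: ModalityData, noise_sd: float, k: int, seed: int
) -> VariationalReplicate:
    """Perturbed copy of a modality for self-alignment.

    Gaussian noise with standard deviation ``noise_sd * sd_f`` is added to
    every feature ``f`` (relative scaling keeps the perturbation comparable
    across features of different magnitude); geodesics are re-computed on
    the perturbed matrix with neighbor count ``k``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scale = data.matrix.std(axis=0, ddof=0)
    noise = rng.standard_normal(data.matrix.shape) * (noise_sd * scale)
    perturbed = ModalityData(
        data.matrix + noise, cell_ids=data.cell_ids, labels=data.labels
    )
    geo, k_used = geodesics_from_points(perturbed, k)
    return VariationalReplicate(
        data=perturbed,
        geodesic=geo,
        noise_sd=noise_sd,
        k_neighbors=k,
        seed=seed,
        k_used=k_used,
    )
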