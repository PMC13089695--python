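"""Cylindrical cuff-electrode geometry and spatial graph construction.

The nerve cuff is a grid of ``n_rings`` rings of ``n_contacts`` contacts
wrapped around the nerve.  Nodes are electrode contacts; edges encode
spatial proximity.  Because the contacts lie on a cylinder, the natural
distance between two contacts is geodesic: the ring offset plus the
*shorter* circumferential arc, so contacts on opposite sides of the seam
of the unrolled grid are still near each other.  The planar Euclidean
distance (which ignores the wrap-around) and a sparsity-matched random
topology are provided as ablation graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CuffLayout",
    "GraphConfig",
    "ElectrodeGraph",
    "geodesic_distance",
    "euclidean_distance",
    "edge_weight",
    "build_graph",
]

METRICS = ("geodesic", "euclidean", "random")


@dataclass(frozen=True)
class CuffLayout:
    """Electrode grid: ``n_rings`` rows along the nerve × ``n_contacts``
    columns around the circumference.  Node indices are row-major:
    ``index = ring * n_contacts + contact``."""

    n_rings: int = 7
    n_contacts: int = 8

    def __post_init__(self):
        if self.n_rings < 1 or self.n_contacts < 1:
            raise ValueError("layout dimensions must be positive")

    @property
    def n_nodes(self) -> int:
        return self.n_rings * self.n_contacts

    def coords(self, node: int) -> tuple[int, int]:
        """Node index -> (ring x, circumferential y)."""
        if not 0 <= node < self.n_nodes:
            raise IndexError(f"node {node} out of range [0, {self.n_nodes})")
        return divmod(node, self.n_contacts)

    def node(self, x: int, y: int) -> int:
        """(ring x, circumferential y) -> node index."""
        if not (0 <= x < self.n_rings and 0 <= y < self.n_contacts):
            raise IndexError(f"coords ({x}, {y}) out of range")
        return x * self.n_contacts + y


@dataclass(frozen=True)
class GraphConfig:
    """Graph construction parameters.

    ``metric`` selects the distance ("geodesic", "euclidean") or a
    sparsity-matched "random" topology; ``k`` is the nearest-neighbour
    count; ``sigma`` the Gaussian distance-decay scale; ``seed`` is used
    only for the random metric.
    """

    metric: str = "geodesic"
    k: int = 5
    sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class ElectrodeGraph:
    """Weighted symmetric adjacency over the cuff contacts.

    Self-loops are excluded here; the graph-convolution layer adds them
    itself during normalization.
    """

    adjacency: np.ndarray
    config: GraphConfig
    layout: CuffLayout

    def __post_init__(self):
        a = self.adjacency
        n = self.layout.n_nodes
        if a.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}, got {a.shape}")

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return int(np.count_nonzero(self.adjacency) // 2)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Undirected edges (i < j) with weights."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(ii, jj)]

    def to_csv(self, path) -> None:
        """Dense header-less CSV, one row per node."""
        np.savetxt(path, self.adjacency, delimiter=",", fmt="%.10g")

    def to_edgelist_tsv(self, path) -> None:
        """TSV columns node_i, node_j, weight with i < j."""
        with open(path, "w") as fh:
            fh.write("node_i\tnode_j\tweight\n")
            for i, j, w in self.edge_list():
                fh.write(f"{i}\t{j}\t{w:.10g}\n")


def geodesic_distance(i: int, j: int, layout: CuffLayout) -> int:
    """Shortest-path distance on the cylindrical grid.

    Ring offset plus the shorter of the two circumferential arcs:
    ``|x_i - x_j| + min(|y_i - y_j|, n_contacts - |y_i - y_j|)``.
    """
    xi, yi = layout.coords(i)
    xj, yj = layout.coords(j)
    dy = abs(yi - yj)
    return abs(xi - xj) + min(dy, layout.n_contacts - dy)


def euclidean_distance(i: int, j: int, layout: CuffLayout) -> float:
    """Planar distance on the unrolled grid; no circumferential wrap."""
    xi, yi = layout.coords(i)
    xj, yj = layout.coords(j)
    return math.hypot(xi - xj, yi - yj)


def edge_weight(d: float, sigma: float) -> float:
    """Gaussian distance kernel exp(-d^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return math.exp(-(d * d) / (2.0 * sigma * sigma))


def _distance_matrix(layout: CuffLayout, metric: str) -> np.ndarray:
    n = layout.n_nodes
    x, y = np.divmod(np.arange(n), layout.n_contacts)
    dx = np.abs(x[:, None] - x[None, :])
    dy = np.abs(y[:, None] - y[None, :])
    if metric == "geodesic":
        return dx + np.minimum(dy, layout.n_contacts - dy)
    return np.sqrt(dx.astype(float) ** 2 + dy.astype(float) ** 2)


def _knn_adjacency(dist: np.ndarray, k: int, sigma: float) -> np.ndarray:
    """Symmetrized (union) k-NN graph with Gaussian weights.

    Equidistant candidates are broken by ascending node index so the
    construction is reproducible.
    """
    n = dist.shape[0]
    adj = np.zeros((n, n))
    idx = np.arange(n)
    for i in range(n):
        order = sorted(np.delete(idx, i), key=lambda j: (dist[i, j], j))
        for j in order[:k]:
            w = edge_weight(float(dist[i, j]), sigma)
            adj[i, j] = w
            adj[j, i] = w
    return adj


def build_graph(layout: CuffLayout, config: GraphConfig) -> ElectrodeGraph:
    """Build the weighted electrode graph for a layout and config.

    For the distance metrics each node first selects its ``k`` nearest
    other nodes; the directed relation is symmetrized by union and
    retained edges carry ``edge_weight(d, sigma)``.  For ``metric ==
    "random"`` the same number of undirected edges as the geodesic graph
    at the same ``k`` is drawn uniformly among node pairs (weights 1),
    preserving sparsity while discarding the spatial prior.
    """
    n = layout.n_nodes
    if not 1 <= config.k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {config.k}")
    if config.metric in ("geodesic", "euclidean"):
        dist = _distance_matrix(layout, config.metric)
        adj = _knn_adjacency(dist, config.k, config.sigma)
    else:
        reference = _knn_adjacency(_distance_matrix(layout, "geodesic"),
                                   config.k, config.sigma)
        n_edges = int(np.count_nonzero(reference) // 2)
        rng = np.random.default_rng(config.seed)
        ii, jj = np.triu_indices(n, k=1)
        chosen = rng.choice(len(ii), size=n_edges, replace=False)
        adj = np.zeros((n, n))
        adj[ii[chosen], jj[chosen]] = 1.0
        adj[jj[chosen], ii[chosen]] = 1.0
    return ElectrodeGraph(adjacency=adj, config=config, layout=layout)
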