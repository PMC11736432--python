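"""Topology analysis of trained masks: modularity, clustering, Louvain
partitions, K-S distance between connection-length distributions, and
position-randomized baselines.

The wiring pattern of the hidden layer is analysed as an unweighted
undirected graph: each recurrent unit is a vertex and an edge {i, j}
exists if either directed connection between i and j is active.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.stats import ks_2samp

from .geometry import SpatialLayout, normalize_distances
from .wiring_cost import SparseNet

__all__ = [
    "mask_to_graph",
    "modularity",
    "clustering_coefficient",
    "louvain_partition",
    "ks_distance",
    "randomize_positions",
    "connection_distance_sample",
]


def mask_to_graph(mask: np.ndarray) -> nx.Graph:
    """Symmetrize a binary connectivity mask into a simple undirected graph."""
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError(f"mask must be square, got {mask.shape}")
    n = mask.shape[0]
    sym = (mask + mask.T) > 0
    np.fill_diagonal(sym, False)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(*np.nonzero(np.triu(sym))))
    return g


def modularity(graph: nx.Graph, partition: dict[int, int]) -> float:
    """Newman modularity Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity is undefined on an empty graph")
    nodes = list(graph.nodes())
    if set(partition) < set(nodes):
        raise ValueError("partition must cover every node")
    A = nx.to_numpy_array(graph, nodelist=nodes)
    k = A.sum(axis=1)
    c = np.array([partition[v] for v in nodes])
    same = c[:, None] == c[None, :]
    return float(np.sum((A - np.outer(k, k) / (2.0 * m)) * same) / (2.0 * m))


def clustering_coefficient(graph: nx.Graph) -> tuple[dict[int, float], float]:
    """Per-node local clustering (0 for degree <= 1) and its average over
    all n nodes."""
    per_node = nx.clustering(graph)
    n = graph.number_of_nodes()
    avg = sum(per_node.values()) / n if n else 0.0
    return per_node, float(avg)


def louvain_partition(graph: nx.Graph, seed: int = 0, restarts: int = 20) -> dict[int, int]:
    """Best-modularity Louvain partition over seeded restarts (deterministic
    for fixed (seed, restarts))."""
    if graph.number_of_edges() == 0:
        raise ValueError("cannot partition an empty graph")
    best_q, best = -np.inf, None
    for r in range(restarts):
        comms = nx.community.louvain_communities(graph, seed=seed + r)
        part = {v: ci for ci, com in enumerate(comms) for v in com}
        q = modularity(graph, part)
        if q > best_q:
            best_q, best = q, part
    return best


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov-Smirnov distance: sup_x |ECDF_a(x) - ECDF_b(x)|."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(ks_2samp(a, b, method="asymp").statistic)


def randomize_positions(net: SparseNet, seed: int | None = None) -> SparseNet:
    """Permute unit coordinates uniformly at random; topology untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(net.n_units)
    layout = SpatialLayout(net.layout.coords[perm])
    return SparseNet(net.mask.copy(), net.weights.copy(), layout)


def connection_distance_sample(
    net: SparseNet,
    normalize: bool = False,
    deduplicate: bool = False,
) -> np.ndarray:
    """Euclidean length of each active connection (unweighted by |w|).

    Each directed connection contributes one value, so reciprocal pairs
    contribute twice unless ``deduplicate``. With ``normalize``, lengths
    are divided by the longest observed separation in the sample.
    """
    mask = net.mask
    if deduplicate:
        mask = np.triu((mask + mask.T) > 0)
        mask = mask & ~np.eye(net.n_units, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("net has no active connections")
    D = net.distance_matrix()
    sample = D[np.asarray(mask, dtype=bool)]
    return normalize_distances(sample) if normalize else sample
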