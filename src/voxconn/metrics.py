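"""Nodal and whole-network metrics on binary voxel networks.

Definitions (unweighted, undirected, no self-loops):

degree
    K(i) = number of neighbors of i.
global efficiency
    Eglob(i) = mean over j != i of 1 / d(i, j), with d the shortest-path
    length by breadth-first search; unreachable pairs contribute 0 (no
    restriction to the largest component).  Network Eglob is the nodal
    mean; it is 1 exactly on a complete graph.
local efficiency
    Eloc(i) = network global efficiency of the subgraph induced on the
    neighbors of i (i excluded); nodes with fewer than two neighbors
    score 0.
clustering / path length
    Standard binary clustering coefficient and mean finite shortest-path
    length; computed only on request since global/local efficiency are
    the primary read-outs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .grid import NodeMap
from .network import BinaryNetwork


@dataclass
class MetricVolume:
    """One scalar per network node for a named metric."""

    metric_name: str              # "K", "Eglob", "Eloc", "C", "L"
    values: np.ndarray            # (n_nodes,)
    node_map: Optional[NodeMap] = None
    meta: dict = field(default_factory=dict)

    @property
    def network_mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def network_sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    def summary(self) -> dict:
        return {"metric": self.metric_name, "mean": self.network_mean,
                "sd": self.network_sd}


def degree(net: BinaryNetwork) -> MetricVolume:
    return MetricVolume("K", net.degrees.astype(float), net.node_map)


def degree_distribution(net: BinaryNetwork):
    """(degree values, probabilities): support = observed degrees."""
    deg = net.degrees
    values, counts = np.unique(deg, return_counts=True)
    return values, counts / deg.size


def _inverse_distance_sums(adj: sp.csr_array) -> np.ndarray:
    """Sum over j != i of 1/d(i, j) for every node, BFS distances."""
    n = adj.shape[0]
    if n < 2:
        return np.zeros(n)
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0      # diagonal and unreachable pairs
    return inv.sum(axis=1)


def global_efficiency(net: BinaryNetwork) -> MetricVolume:
    n = net.n_nodes
    vals = (_inverse_distance_sums(net.adjacency) / (n - 1)
            if n >= 2 else np.zeros(n))
    return MetricVolume("Eglob", vals, net.node_map)


def _subgraph_efficiency(adj_dense_bool: np.ndarray) -> float:
    """Network global efficiency of a small dense adjacency."""
    m = adj_dense_bool.shape[0]
    if m < 2:
        return 0.0
    sub = sp.csr_array(adj_dense_bool)
    total = _inverse_distance_sums(sub).sum()
    return float(total / (m * (m - 1)))


def local_efficiency(net: BinaryNetwork) -> MetricVolume:
    adj = net.adjacency.tocsr()
    dense = None
    vals = np.zeros(net.n_nodes)
    indptr, indices = adj.indptr, adj.indices
    for i in range(net.n_nodes):
        nb = indices[indptr[i]:indptr[i + 1]]
        if nb.size < 2:
            continue
        if dense is None:
            dense = adj.toarray().astype(bool)
        vals[i] = _subgraph_efficiency(dense[np.ix_(nb, nb)])
    return MetricVolume("Eloc", vals, net.node_map)


def clustering_and_pathlength(net: BinaryNetwork):
    """Optional metrics: clustering coefficient C and path length L.

    C(i) counts connected neighbor pairs of i over all neighbor pairs;
    L(i) is the mean finite shortest-path distance from i to the other
    reachable nodes (0 for isolates).
    """
    adj = net.adjacency.tocsr()
    n = net.n_nodes
    dense = adj.toarray().astype(bool)
    deg = net.degrees
    c_vals = np.zeros(n)
    indptr, indices = adj.indptr, adj.indices
    for i in range(n):
        nb = indices[indptr[i]:indptr[i + 1]]
        if nb.size < 2:
            continue
        links = np.count_nonzero(dense[np.ix_(nb, nb)]) / 2
        c_vals[i] = 2.0 * links / (nb.size * (nb.size - 1))
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    np.fill_diagonal(dist, np.inf)
    l_vals = np.zeros(n)
    for i in range(n):
        finite = np.isfinite(dist[i])
        if finite.any():
            l_vals[i] = dist[i, finite].mean()
    return (MetricVolume("C", c_vals, net.node_map),
            MetricVolume("L", l_vals, net.node_map))


def metric_to_volume(metric: MetricVolume, missing=np.nan) -> np.ndarray:
    """Scatter nodal values into a 3-D volume on the session grid."""
    if metric.node_map is None:
        raise ValueError("metric has no node map; cannot place in a volume")
    return metric.node_map.to_volume(metric.values, missing=missing)
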