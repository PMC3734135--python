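"""All-pairs voxel correlation networks and N = K**S density thresholding.

The binarization rule fixes the connection density rather than the
correlation cutoff: for a network of N nodes and exponent S, the
correlation threshold r_th is chosen so the mean degree K satisfies
K = N**(1/S).  Equivalently, r_th is the value of the m-th largest
off-diagonal correlation with m = floor(N * N**(1/S) / 2); keeping
edges with r >= r_th (signed r -- the threshold is a lower bound, so
strong negative correlations are excluded) realizes exactly m edges
when there are no ties at the cutoff, and m plus the tie block when
there are.  This keeps density comparable across sessions and subjects
whose node counts differ.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .grid import NodeMap
from .preprocess import VoxelMatrix

log = logging.getLogger(__name__)

DEFAULT_BLOCK = 1024


@dataclass
class BinaryNetwork:
    """Thresholded symmetric adjacency plus the rule that produced it."""

    adjacency: sp.csr_array       # boolean, symmetric, zero diagonal
    n_nodes: int
    r_threshold: float
    S: float
    node_map: Optional[NodeMap] = None
    meta: dict = field(default_factory=dict)

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.edge_count / self.n_nodes

    def to_dense(self) -> np.ndarray:
        return self.adjacency.toarray().astype(bool)

    def write(self, prefix):
        """Edge-list TSV plus a JSON metadata sidecar."""
        prefix = Path(prefix)
        coo = sp.triu(self.adjacency, k=1).tocoo()
        edges = np.column_stack([coo.row, coo.col])
        edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
        np.savetxt(str(prefix) + "_edges.tsv", edges, fmt="%d",
                   delimiter="\t", header="node_i\tnode_j", comments="")
        meta = {"n_nodes": self.n_nodes, "S": self.S,
                "r_threshold": self.r_threshold,
                "edge_count": self.edge_count,
                "mean_degree": self.mean_degree, **self.meta}
        with open(str(prefix) + "_network.json", "w") as fh:
            json.dump(meta, fh, indent=1)


def target_mean_degree(n_nodes: int, S: float) -> float:
    """Mean degree implied by N = K**S, i.e. K = N**(1/S)."""
    return float(n_nodes) ** (1.0 / S)


def _standardize(values: np.ndarray) -> np.ndarray:
    """Column-standardized copy; zero-variance columns become all-zero."""
    x = np.asarray(values, dtype=np.float64)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    dead = sd == 0
    if dead.any():
        log.warning("%d zero-variance column(s): correlation set to 0",
                    int(dead.sum()))
    sd = np.where(dead, 1.0, sd)
    return x / (sd * np.sqrt(x.shape[0]))


def correlation_matrix(matrix) -> np.ndarray:
    """Dense Pearson correlation matrix over all voxel pairs.

    Accepts a :class:`VoxelMatrix` or a raw (t, n) array.  Zero-variance
    columns correlate 0 with everything; the diagonal is 1.
    """
    values = matrix.values if isinstance(matrix, VoxelMatrix) else matrix
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlations")
    z = _standardize(values)
    corr = z.T @ z
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr


def _upper_values(corr: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(corr.shape[0], k=1)
    return corr[iu]


def solve_threshold(correlations, S: float, n_nodes: Optional[int] = None
                    ) -> float:
    """Correlation cutoff whose inclusive thresholding yields K ~ N**(1/S).

    ``correlations`` may be a dense square matrix or a 1-D array of the
    upper-triangle values (then ``n_nodes`` may be given; otherwise it
    is inferred from the length).
    """
    correlations = np.asarray(correlations)
    if correlations.ndim == 2:
        n = correlations.shape[0]
        vals = _upper_values(correlations)
    else:
        vals = correlations
        if n_nodes is None:
            n = int(round((1 + np.sqrt(1 + 8 * vals.size)) / 2))
            if n * (n - 1) // 2 != vals.size:
                raise ValueError("length is not a triangular number; "
                                 "pass n_nodes")
        else:
            n = n_nodes
    if n < 2 or S <= 1:
        raise ValueError("need n_nodes >= 2 and S > 1")
    t = n * target_mean_degree(n, S) / 2.0
    # relative epsilon so analytically integer targets (e.g. 1000**(4/3)/2)
    # are not floored down by floating-point error in the power
    m = int(np.floor(t + 1e-9 * max(1.0, t)))
    if m < 1:
        raise ValueError("network would be empty: target edge count < 1")
    m = min(m, vals.size)
    # m-th largest value; ties at this value are included by binarize
    return float(np.partition(vals, vals.size - m)[vals.size - m])


def binarize(correlations: np.ndarray, r_threshold: float, S: float,
             node_map: Optional[NodeMap] = None) -> BinaryNetwork:
    """Edge (i, j) iff r(i, j) >= r_threshold, i != j (inclusive cutoff)."""
    corr = np.asarray(correlations)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlations must be a square matrix")
    n = corr.shape[0]
    upper = np.triu(corr >= r_threshold, k=1)
    adj = sp.csr_array(upper | upper.T)
    net = BinaryNetwork(adjacency=adj, n_nodes=n,
                        r_threshold=float(r_threshold), S=float(S),
                        node_map=node_map)
    net.meta.update(edge_count=net.edge_count, mean_degree=net.mean_degree)
    return net


def _block_correlations(z: np.ndarray, block: int):
    """Yield (row_start, corr_block) of the standardized product."""
    n = z.shape[1]
    for start in range(0, n, block):
        stop = min(start + block, n)
        blk = z[:, start:stop].T @ z
        np.clip(blk, -1.0, 1.0, out=blk)
        yield start, blk


def build_network(matrix, S: float, block_size: int = DEFAULT_BLOCK,
                  r_threshold: Optional[float] = None) -> BinaryNetwork:
    """Correlate, solve the density threshold, and binarize -- blockwise.

    The dense N x N correlation matrix is never materialized: blocks of
    rows are computed twice (once to collect upper-triangle values for
    the quantile, once to emit edges), so memory stays O(N * block +
    N**2 / 2 values) regardless of N.
    """
    values = matrix.values if isinstance(matrix, VoxelMatrix) else matrix
    node_map = matrix.node_map if isinstance(matrix, VoxelMatrix) else None
    values = np.asarray(values, dtype=np.float64)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 time points for correlations")
    n = values.shape[1]
    z = _standardize(values)

    if r_threshold is None:
        dtype = np.float64 if n <= 4096 else np.float32
        parts = []
        for start, blk in _block_correlations(z, block_size):
            for r in range(blk.shape[0]):
                parts.append(blk[r, start + r + 1:].astype(dtype, copy=True))
        vals = np.concatenate(parts) if parts else np.empty(0, dtype)
        del parts
        r_threshold = solve_threshold(vals, S, n_nodes=n)
        del vals

    rows, cols = [], []
    for start, blk in _block_correlations(z, block_size):
        for r in range(blk.shape[0]):
            i = start + r
            js = np.nonzero(blk[r, i + 1:] >= r_threshold)[0] + i + 1
            rows.append(np.full(js.size, i, dtype=np.int64))
            cols.append(js.astype(np.int64))
    rows = np.concatenate(rows) if rows else np.empty(0, np.int64)
    cols = np.concatenate(cols) if cols else np.empty(0, np.int64)
    data = np.ones(rows.size, dtype=bool)
    upper = sp.coo_array((data, (rows, cols)), shape=(n, n)).tocsr()
    adj = (upper + upper.T).astype(bool).tocsr()
    adj = sp.csr_array(adj)
    net = BinaryNetwork(adjacency=adj, n_nodes=n,
                        r_threshold=float(r_threshold), S=float(S),
                        node_map=node_map)
    net.meta.update(edge_count=net.edge_count, mean_degree=net.mean_degree)
    return net
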