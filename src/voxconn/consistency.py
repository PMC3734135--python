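"""Session- and subject-level consistency of top-ranked network nodes.

Per subject and condition: take each session's top fraction of nodes by
a metric (e.g. top 20% by degree), count per voxel the fraction of
sessions it survives in, threshold that fraction (>= 3 of 5 sessions by
default), then count across subjects how many subjects retain each
voxel -- a "meta" consistency map.  The same machinery maps the nodes
connected to a region's top metric nodes and their consistency across
sessions and subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import NodeMap
from .metrics import MetricVolume
from .network import BinaryNetwork


@dataclass
class ConsistencyVolume:
    """Per-node fraction of sessions (or subjects) in [0, 1]."""

    values: np.ndarray            # (n_nodes,) fractions
    denominator: int              # number of sessions or subjects
    level: str                    # "session" or "subject"
    node_map: Optional[NodeMap] = None
    source_metric: str = ""
    top_fraction: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def counts(self) -> np.ndarray:
        return np.rint(self.values * self.denominator).astype(int)


def top_fraction_mask(metric: MetricVolume, fraction: float,
                      within: Optional[np.ndarray] = None) -> np.ndarray:
    """Boolean node set of the ceil(fraction * N) highest-valued nodes.

    Ties at the cut are resolved deterministically: nodes are ordered by
    (value descending, node index ascending) and the cut is exact.  With
    ``within`` (a boolean node mask) the ranking is restricted to that
    subset and N counts only its nodes.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    values = np.asarray(metric.values, dtype=float)
    if values.size == 0:
        raise ValueError("empty metric")
    pool = (np.arange(values.size) if within is None
            else np.flatnonzero(np.asarray(within, bool)))
    if pool.size == 0:
        raise ValueError("restriction mask selects no nodes")
    n_top = int(np.ceil(fraction * pool.size))
    order = pool[np.lexsort((pool, -values[pool]))]
    out = np.zeros(values.size, dtype=bool)
    out[order[:n_top]] = True
    return out


def _check_common(maps: Sequence[Optional[NodeMap]]):
    ref = next((m for m in maps if m is not None), None)
    for m in maps:
        if m is not None and ref is not None and not m.same_grid(ref):
            raise ValueError("inputs are not on a common node map")
    return ref


def session_overlap(masks: Sequence[np.ndarray],
                    node_map: Optional[NodeMap] = None,
                    source_metric: str = "", top_fraction: float = np.nan
                    ) -> ConsistencyVolume:
    """Per node, the fraction of sessions whose mask contains it."""
    if len(masks) == 0:
        raise ValueError("need at least one session mask")
    stack = np.stack([np.asarray(m, bool) for m in masks])
    if stack.ndim != 2:
        raise ValueError("session masks must be per-node boolean vectors")
    return ConsistencyVolume(values=stack.mean(axis=0),
                             denominator=stack.shape[0], level="session",
                             node_map=node_map, source_metric=source_metric,
                             top_fraction=top_fraction)


def threshold_consistency(cv: ConsistencyVolume,
                          min_fraction: float) -> np.ndarray:
    """Nodes whose consistency fraction is >= min_fraction (inclusive)."""
    if not (0.0 < min_fraction <= 1.0):
        raise ValueError("min_fraction must be in (0, 1]")
    return cv.values >= min_fraction


def subject_meta_map(subject_sets: Sequence[np.ndarray],
                     node_map: Optional[NodeMap] = None,
                     source_metric: str = "", top_fraction: float = np.nan
                     ) -> ConsistencyVolume:
    """Per node, the fraction of subjects whose set contains it."""
    if len(subject_sets) == 0:
        raise ValueError("need at least one subject set")
    stack = np.stack([np.asarray(m, bool) for m in subject_sets])
    if stack.ndim != 2:
        raise ValueError("subject sets must be per-node boolean vectors")
    return ConsistencyVolume(values=stack.mean(axis=0),
                             denominator=stack.shape[0], level="subject",
                             node_map=node_map, source_metric=source_metric,
                             top_fraction=top_fraction)


def connected_to_top_nodes(net: BinaryNetwork, top_nodes: np.ndarray,
                           include_top: bool = False) -> np.ndarray:
    """Nodes adjacent to at least one node of ``top_nodes``.

    A top node is included only when it is adjacent to another top node
    (there are no self-edges); with ``include_top`` the whole top set is
    added to the result.
    """
    top = np.asarray(top_nodes, bool)
    if top.size != net.n_nodes:
        raise ValueError("top_nodes length does not match the network")
    hit = net.adjacency @ top.astype(np.int64) > 0
    return hit | top if include_top else hit


def group_connectivity_map(subject_sets: Sequence[np.ndarray],
                           subject_threshold: float = 0.5) -> np.ndarray:
    """Nodes connected in >= subject_threshold of subjects (inclusive)."""
    if len(subject_sets) == 0:
        raise ValueError("need at least one subject input")
    if not (0.0 < subject_threshold <= 1.0):
        raise ValueError("subject_threshold must be in (0, 1]")
    stack = np.stack([np.asarray(m, bool) for m in subject_sets])
    return stack.mean(axis=0) >= subject_threshold
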