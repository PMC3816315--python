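"""Cluster extraction and evaluation across the coarsening hierarchy.

A supernode at any level expands to its constituent reads by nested descent
through the node_map_inverse arrays; the clusters at a level therefore
partition the read set, with cluster sizes equal to the node weights.
Clusters are scored against ground truth by majority vote: each cluster (and
all its reads) is classified as the most frequent source genome among its
reads, and the error rate is the percentage of misclassified reads.

The module also recovers a read ordering by traversing a reduced graph and
relabels the level-0 graph accordingly, so that edges with common endpoints
receive nearby ids (a locality-improving re-numbering).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .coarsen import Hierarchy
from .graph import OverlapGraph, build_graph_from_edges


@dataclass
class ClusterSet:
    level: int
    clusters: dict[int, set[int]]

    @property
    def n_reads(self) -> int:
        return sum(len(c) for c in self.clusters.values())


def expand_to_reads(hierarchy: Hierarchy, level: int, z: int) -> list[int]:
    """All level-0 read ids descended from supernode z at ``level``.

    Depth-first descent through the node_map_inverse arrays, skipping -1
    sentinels; at level 0 the node label is the read id.  Order is the
    recursion (preorder) order.
    """
    if not 0 <= level < hierarchy.n_levels:
        raise IndexError(f"level {level} out of range")
    if not 0 <= z < hierarchy.levels[level].graph.n:
        raise IndexError(f"node {z} out of range at level {level}")
    out: list[int] = []
    stack: list[tuple[int, int]] = [(level, z)]
    while stack:
        lv, node = stack.pop()
        if lv == 0:
            out.append(node)
            continue
        nmi = hierarchy.levels[lv].node_map_inverse
        u = int(nmi[2 * node])
        v = int(nmi[2 * node + 1])
        if v >= 0:
            stack.append((lv - 1, v))
        stack.append((lv - 1, u))
    return out


def clusters_at(hierarchy: Hierarchy, level: int) -> ClusterSet:
    """The read partition induced by the supernodes of one level."""
    if not 0 <= level < hierarchy.n_levels:
        raise IndexError(f"level {level} out of range")
    n_nodes = hierarchy.levels[level].graph.n
    return ClusterSet(
        level=level,
        clusters={z: set(expand_to_reads(hierarchy, level, z)) for z in range(n_nodes)},
    )


def majority_labels(clusters: ClusterSet, truth: Sequence[str]) -> dict[int, str]:
    """Most frequent truth label per cluster; ties -> lexicographically least."""
    out: dict[int, str] = {}
    for z, members in clusters.clusters.items():
        counts = Counter()
        for r in members:
            if r >= len(truth) or truth[r] is None:
                raise ValueError(f"missing truth label for read {r}")
            counts[truth[r]] += 1
        top = max(counts.values())
        out[z] = min(lab for lab, c in counts.items() if c == top)
    return out


def error_rate(clusters: ClusterSet, truth: Sequence[str]) -> float:
    """Percentage of reads whose truth label differs from their cluster's
    majority label."""
    if clusters.n_reads == 0:
        raise ValueError("empty read set")
    labels = majority_labels(clusters, truth)
    wrong = 0
    for z, members in clusters.clusters.items():
        lab = labels[z]
        wrong += sum(1 for r in members if truth[r] != lab)
    return 100.0 * wrong / clusters.n_reads


def error_table(
    hierarchy: Hierarchy, truth: Optional[Sequence[str]]
) -> list[dict]:
    """Per-level node count, edge count and (with truth) error rate."""
    rows = []
    for i, lv in enumerate(hierarchy.levels):
        row: dict = {"level": i, "nodes": lv.graph.n, "edges": lv.graph.m}
        if truth is not None:
            row["error_rate"] = error_rate(clusters_at(hierarchy, i), truth)
        rows.append(row)
    return rows


def traversal_order(hierarchy: Hierarchy, level: int) -> np.ndarray:
    """Read permutation from a breadth-first traversal of the reduced graph.

    Components are seeded at the unvisited supernode of largest node weight
    (ties: smallest id); neighbors are enqueued in stored descending-weight
    order; each visited supernode is expanded to its reads in recursion
    order.  The result is a permutation of 0..|V_0|-1.
    """
    lv = hierarchy.levels[level]
    G = lv.graph
    nw = lv.node_weights
    seed_order = np.lexsort((np.arange(G.n), -nw))
    visited = np.zeros(G.n, dtype=bool)
    out: list[int] = []
    for s in seed_order:
        if visited[s]:
            continue
        visited[s] = True
        queue = deque([int(s)])
        while queue:
            u = queue.popleft()
            out.extend(expand_to_reads(hierarchy, level, u))
            dsts, _ = G.neighbors(u)
            for v in dsts:
                if not visited[v]:
                    visited[v] = True
                    queue.append(int(v))
    return np.asarray(out, dtype=np.int64)


def locality_score(G: OverlapGraph) -> float:
    """Mean |src - dst| over undirected edges (0 for an edgeless graph)."""
    src, dst, _ = G.edge_arrays()
    if src.size == 0:
        return 0.0
    return float(np.abs(src - dst).mean())


def relabel_edges(G0: OverlapGraph, order: np.ndarray) -> OverlapGraph:
    """Renumber nodes so that ``order[i]`` becomes node i.

    The result is isomorphic to the input (degree multiset and total weight
    preserved); when ``order`` comes from :func:`traversal_order`, endpoints
    of common-supernode edges end up close together.
    """
    order = np.asarray(order, dtype=np.int64)
    if (
        order.size != G0.n
        or order.min(initial=0) < 0
        or np.unique(order).size != G0.n
    ):
        raise ValueError("order must be a permutation of the graph's nodes")
    new_id = np.empty(G0.n, dtype=np.int64)
    new_id[order] = np.arange(G0.n, dtype=np.int64)
    src, dst, w = G0.edge_arrays()
    ident = None
    if G0.identity is not None:
        # recover per-undirected-edge identity aligned with edge_arrays()
        src_all = np.repeat(np.arange(G0.n, dtype=np.int64), np.diff(G0.offsets))
        keep = src_all < G0.dst
        ident = G0.identity[keep]
    return build_graph_from_edges(G0.n, new_id[src], new_id[dst], w, identity=ident)
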