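"""The overlap graph: flat-array adjacency with weight-sorted edge sets.

One node per read; one undirected edge per accepted overlap, weighted by the
alignment overlap length.  Adjacency is stored CSR-style: a flat destination
array, a parallel weight array, and a per-node offset array, with every
undirected edge appearing once per endpoint.  Within each node's edge set,
edges are sorted by descending weight (ties broken by ascending destination
id) so that the heaviest overlap of a node is always first — the order the
coarsening stage visits neighbors in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .seqio import OverlapTable


@dataclass
class OverlapGraph:
    n: int
    offsets: np.ndarray  # int64, length n+1, offsets[-1] == 2*m
    dst: np.ndarray      # int64, length 2*m
    w: np.ndarray        # int64, length 2*m
    identity: Optional[np.ndarray] = None  # float64, level-0 graphs only

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return self.dst.size // 2

    def neighbors(self, u: int):
        """(destination, weight) arrays for u, in nonincreasing weight order."""
        if not 0 <= u < self.n:
            raise IndexError(f"node {u} out of range [0, {self.n})")
        lo, hi = self.offsets[u], self.offsets[u + 1]
        return self.dst[lo:hi], self.w[lo:hi]

    def degree(self, u: int) -> int:
        return int(self.offsets[u + 1] - self.offsets[u])

    def iter_edges(self, with_identity: bool = False) -> Iterator[tuple]:
        """Yield each undirected edge once, as (u, v, w[, identity]) with u < v."""
        for u in range(self.n):
            lo, hi = int(self.offsets[u]), int(self.offsets[u + 1])
            for t in range(lo, hi):
                v = int(self.dst[t])
                if u < v:
                    if with_identity:
                        ident = float(self.identity[t]) if self.identity is not None else 0.0
                        yield u, v, int(self.w[t]), ident
                    else:
                        yield u, v, int(self.w[t])

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(src, dst, w) with each undirected edge once (src < dst)."""
        src_all = np.repeat(np.arange(self.n, dtype=np.int64), np.diff(self.offsets))
        keep = src_all < self.dst
        return src_all[keep], self.dst[keep], self.w[keep]


def neighbors(G: OverlapGraph, u: int):
    return G.neighbors(u)


def total_edge_weight(G: OverlapGraph) -> int:
    """Sum of weights over undirected edges (each counted once)."""
    return int(G.w.sum()) // 2


def build_graph_from_edges(
    n: int,
    src: Sequence[int],
    dst: Sequence[int],
    w: Sequence[int],
    identity: Optional[Sequence[float]] = None,
) -> OverlapGraph:
    """Assemble the symmetric CSR layout from a deduplicated edge list.

    Callers must supply each undirected edge exactly once, without
    self-loops; ids must lie in [0, n).
    """
    src = np.asarray(src, dtype=np.int64).reshape(-1)
    dst = np.asarray(dst, dtype=np.int64).reshape(-1)
    w = np.asarray(w, dtype=np.int64).reshape(-1)
    if src.size:
        if src.min() < 0 or dst.min() < 0 or max(src.max(), dst.max()) >= n:
            raise ValueError("edge endpoint out of range")
        if np.any(src == dst):
            raise ValueError("self-loop in edge list")
    ident = None
    if identity is not None:
        ident = np.asarray(identity, dtype=np.float64).reshape(-1)
    # mirror each edge, then sort by (src asc, weight desc, dst asc)
    s2 = np.concatenate([src, dst])
    d2 = np.concatenate([dst, src])
    w2 = np.concatenate([w, w])
    order = np.lexsort((d2, -w2, s2))
    s2, d2, w2 = s2[order], d2[order], w2[order]
    offsets = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(s2, minlength=n), out=offsets[1:])
    i2 = None
    if ident is not None:
        i2 = np.concatenate([ident, ident])[order]
    return OverlapGraph(n=n, offsets=offsets, dst=d2, w=w2, identity=i2)


def build_graph(n: int, table: OverlapTable) -> OverlapGraph:
    """Build the level-0 overlap graph from an overlap table.

    Initial edge weight is the alignment overlap length.  Duplicate records
    for the same unordered pair are collapsed keeping the longest alignment
    (ties: highest identity).
    """
    best: dict[tuple[int, int], tuple[int, float]] = {}
    for r in table:
        if not (0 <= r.query_id < n and 0 <= r.ref_id < n):
            raise ValueError(f"read id out of range in record {r}")
        key = (min(r.query_id, r.ref_id), max(r.query_id, r.ref_id))
        cur = best.get(key)
        cand = (r.alignment_length, r.identity)
        if cur is None or cand > cur:
            best[key] = cand
    src = [k[0] for k in best]
    dst = [k[1] for k in best]
    w = [v[0] for v in best.values()]
    ident = [v[1] for v in best.values()]
    return build_graph_from_edges(n, src, dst, w, identity=ident)


def merge_parallel_edges(
    edges: Sequence[tuple[int, int, int]],
) -> list[tuple[int, int, int]]:
    """Merge edges with identical unordered endpoints, summing their weights.

    Self-loops must have been dropped by the caller and are rejected here.
    Output is one edge per unordered pair (u < v), sorted by
    (src asc, weight desc, dst asc).
    """
    acc: dict[tuple[int, int], int] = {}
    for u, v, w in edges:
        if u == v:
            raise ValueError(f"self-loop ({u},{u}) passed to merge_parallel_edges")
        key = (u, v) if u < v else (v, u)
        acc[key] = acc.get(key, 0) + w
    out = [(u, v, w) for (u, v), w in acc.items()]
    out.sort(key=lambda e: (e[0], -e[2], e[1]))
    return out
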