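"""Heavy Edge Matching graph coarsening.

Each iteration matches nodes greedily to their heaviest available neighbor —
heaviest-keyed nodes visited first, randomly within equal keys — subject to
an edge-density constraint, then contracts the matching: matched pairs merge
into supernodes, edges are relabeled through node_map, self-mapped edges are
dropped and parallel edges merged with summed weights.  Bookkeeping arrays
(node_weights, edge_weights, node_map, node_map_inverse) let any coarse node
be expanded back to its constituent reads.  Iteration stops when the matched
fraction falls below ``min_match_ratio``.

Density of a prospective supernode z = u+v with combined node weight
s = nw[u]+nw[v]:

    edge_density(u, v) = 2*(ew[u] + ew[v] + w(u,v)) / (s*(s-1))

i.e. the internal level-0 edge weight of z normalized by its number of node
pairs.  For two singleton reads this reduces to the overlap length itself,
so a density threshold of 50 admits only pairs overlapping by more than
50 bp at level 0 — while summed parallel-edge weights let well-covered
regions keep merging at coarser levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import hem_match_pass
from .graph import OverlapGraph, build_graph_from_edges, merge_parallel_edges


@dataclass
class CoarsenParams:
    min_density: float = 50.0
    min_match_ratio: float = 0.01
    min_edge_weight: int = 0
    passes: int = 1
    seed: int = 0
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.min_match_ratio <= 1:
            raise ValueError("min_match_ratio must lie in (0, 1]")
        if self.min_density < 0:
            raise ValueError("min_density must be >= 0")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")


@dataclass
class Matching:
    pairs: list[tuple[int, int]]
    unmatched: list[int]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for u, v in self.pairs:
            if u in seen or v in seen or u == v:
                raise ValueError("matching has a repeated or degenerate node")
            seen.update((u, v))


@dataclass
class CoarseningLevel:
    """One graph of the series with its per-level bookkeeping arrays.

    node_weights[u]: number of level-0 descendants of u.
    edge_weights[u]: total level-0 edge weight internal to u.
    node_map[u]:     supernode label of u in the next level (last level: None).
    node_map_inverse[2z], [2z+1]: the two children of z in the previous level,
                     -1 when z has a single child (level 0: None).
    matching:        the Matching applied to this level (last level: None).
    """

    graph: OverlapGraph
    node_weights: np.ndarray
    edge_weights: np.ndarray
    node_map: Optional[np.ndarray] = None
    node_map_inverse: Optional[np.ndarray] = None
    matching: Optional[Matching] = None

    def __post_init__(self) -> None:
        n = self.graph.n
        if self.node_weights.size != n or self.edge_weights.size != n:
            raise ValueError("node/edge weight arrays must have one entry per node")
        if self.node_map_inverse is not None and self.node_map_inverse.size != 2 * n:
            raise ValueError("node_map_inverse must have length 2*|V|")


@dataclass
class Hierarchy:
    """The series G_0..G_N with all per-level bookkeeping."""

    levels: list[CoarseningLevel]
    params: CoarsenParams
    seed: int

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def node_counts(self) -> list[int]:
        return [lv.graph.n for lv in self.levels]

    def edge_counts(self) -> list[int]:
        return [lv.graph.m for lv in self.levels]


def edge_density(nw_u: int, ew_u: int, nw_v: int, ew_v: int, w_uv: int) -> float:
    """Internal weight density of the supernode formed by merging u and v."""
    if nw_u < 1 or nw_v < 1:
        raise ValueError("node weights must be >= 1")
    s = nw_u + nw_v
    return 2.0 * (ew_u + ew_v + w_uv) / (s * (s - 1.0))


def visit_order(
    G: OverlapGraph,
    rng: np.random.Generator,
    restrict_to: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Node visit sequence: heaviest incident edge first, shuffled within ties.

    The key of a node is the weight of its heaviest incident edge (0 when
    isolated); keys are visited in descending order with a seeded shuffle
    inside each equal-key tier.
    """
    if restrict_to is None:
        nodes = np.arange(G.n, dtype=np.int64)
    else:
        nodes = np.asarray(restrict_to, dtype=np.int64)
    keys = np.zeros(G.n, dtype=np.int64)
    has_edge = np.diff(G.offsets) > 0
    keys[has_edge] = G.w[G.offsets[:-1][has_edge]]  # first = heaviest (sorted sets)
    perm = rng.permutation(nodes)
    return perm[np.argsort(-keys[perm], kind="stable")]


def hem_match(
    G: OverlapGraph,
    nw: np.ndarray,
    ew: np.ndarray,
    params: CoarsenParams,
    rng: np.random.Generator,
) -> Matching:
    """Greedy heavy-edge matching under the density constraint.

    Each unmatched node, in visit order, scans its neighbors from heaviest:
    the scan stops when the weight drops below ``min_edge_weight``; matched
    neighbors and neighbors failing edge_density > min_density are skipped;
    the first surviving neighbor is taken.  ``passes`` sweeps revisit
    still-unmatched nodes with a fresh shuffle.
    """
    matched = np.full(G.n, -1, dtype=np.int64)
    restrict = None
    for _ in range(params.passes):
        order = visit_order(G, rng, restrict_to=restrict)
        hem_match_pass(
            order,
            G.offsets,
            G.dst,
            G.w,
            np.asarray(nw, dtype=np.int64),
            np.asarray(ew, dtype=np.int64),
            int(params.min_edge_weight),
            float(params.min_density),
            matched,
        )
        restrict = np.flatnonzero(matched < 0)
        if restrict.size == 0:
            break
    pairs = [(int(u), int(matched[u])) for u in range(G.n) if matched[u] > u]
    unmatched = [int(u) for u in np.flatnonzero(matched < 0)]
    return Matching(pairs=pairs, unmatched=unmatched)


def match_ratio(M: Matching, G: OverlapGraph) -> float:
    """Fraction of nodes successfully matched: 2|pairs| / |V|."""
    if G.n == 0:
        raise ValueError("empty graph")
    return 2.0 * len(M.pairs) / G.n


def contract(
    G: OverlapGraph, M: Matching, nw: np.ndarray, ew: np.ndarray
) -> tuple[np.ndarray, CoarseningLevel]:
    """Contract a matching into the next coarser level.

    Supernode ids are allocated scanning old ids in ascending order, at the
    first-seen member of each pair and at each unmatched node.  Returns
    (node_map for the current level, the new CoarseningLevel).
    """
    n = G.n
    partner = np.full(n, -1, dtype=np.int64)
    for u, v in M.pairs:
        if not (0 <= u < n and 0 <= v < n):
            raise ValueError("matching references a node outside the graph")
        partner[u] = v
        partner[v] = u
    node_map = np.full(n, -1, dtype=np.int64)
    children: list[tuple[int, int]] = []
    z = 0
    for u in range(n):
        if node_map[u] >= 0:
            continue
        v = int(partner[u])
        node_map[u] = z
        if v >= 0:
            node_map[v] = z
            children.append((u, v))
        else:
            children.append((u, -1))
        z += 1
    n_new = z
    new_nw = np.zeros(n_new, dtype=np.int64)
    new_ew = np.zeros(n_new, dtype=np.int64)
    nmi = np.empty(2 * n_new, dtype=np.int64)
    # weight of the matched edge, looked up in the current adjacency
    for zi, (u, v) in enumerate(children):
        nmi[2 * zi] = u
        nmi[2 * zi + 1] = v
        if v < 0:
            new_nw[zi] = nw[u]
            new_ew[zi] = ew[u]
        else:
            dsts, ws = G.neighbors(u)
            hit = np.flatnonzero(dsts == v)
            if hit.size == 0:
                raise ValueError(f"matching pair ({u},{v}) is not an edge")
            w_uv = int(ws[hit[0]])
            new_nw[zi] = nw[u] + nw[v]
            new_ew[zi] = ew[u] + ew[v] + w_uv
    src, dst, w = G.edge_arrays()
    ns, nd = node_map[src], node_map[dst]
    keep = ns != nd  # self-mapped edges are dropped
    merged = merge_parallel_edges(list(zip(ns[keep].tolist(), nd[keep].tolist(), w[keep].tolist())))
    if merged:
        ms, md, mw = zip(*merged)
    else:
        ms, md, mw = (), (), ()
    new_graph = build_graph_from_edges(n_new, ms, md, mw)
    level = CoarseningLevel(
        graph=new_graph,
        node_weights=new_nw,
        edge_weights=new_ew,
        node_map_inverse=nmi,
    )
    return node_map, level


def initial_level(G0: OverlapGraph) -> CoarseningLevel:
    """Level 0: every node is a single read (nw=1, ew=0)."""
    return CoarseningLevel(
        graph=G0,
        node_weights=np.ones(G0.n, dtype=np.int64),
        edge_weights=np.zeros(G0.n, dtype=np.int64),
    )


def coarsen(
    G0: OverlapGraph,
    params: CoarsenParams,
    out_dir: Optional[str] = None,
) -> Hierarchy:
    """Iteratively match and contract until the match ratio falls below the
    minimum (or the iteration cap).  Deterministic given ``params.seed``.

    When ``out_dir`` is given every level is persisted via
    :func:`ovlcoarse.seqio.write_level` as it is produced.
    """
    from .seqio import write_level

    rng = np.random.default_rng(params.seed)
    levels = [initial_level(G0)]
    for _ in range(params.max_iterations):
        cur = levels[-1]
        M = hem_match(cur.graph, cur.node_weights, cur.edge_weights, params, rng)
        if match_ratio(M, cur.graph) < params.min_match_ratio:
            break
        node_map, new_level = contract(cur.graph, M, cur.node_weights, cur.edge_weights)
        cur.node_map = node_map
        cur.matching = M
        levels.append(new_level)
    hier = Hierarchy(levels=levels, params=params, seed=params.seed)
    if out_dir is not None:
        for i, lv in enumerate(levels):
            write_level(lv, out_dir, i)
    return hier


def read_hierarchy(base_dir: str, params: Optional[CoarsenParams] = None) -> Hierarchy:
    """Load a persisted hierarchy (all level_<i>/ groups under base_dir)."""
    import os

    from .seqio import read_level

    levels = []
    i = 0
    while os.path.isdir(os.path.join(base_dir, f"level_{i}")):
        levels.append(read_level(base_dir, i))
        i += 1
    if not levels:
        raise FileNotFoundError(f"no level_0 directory under {base_dir}")
    return Hierarchy(levels=levels, params=params or CoarsenParams(), seed=(params.seed if params else 0))
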