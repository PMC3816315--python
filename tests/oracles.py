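"""Independent test oracles: naive constructions kept deliberately separate
from the package's implementation paths."""

from __future__ import annotations

import numpy as np


def naive_suffix_array(text: str) -> list[int]:
    """Sort all suffixes directly."""
    return sorted(range(len(text)), key=lambda i: text[i:])


def full_overlap_dp(a: str, b: str):
    """Quadratic overlap alignment: free end gaps, +1/-1/-1 scoring.

    Tie rules mirror the documented contract: diagonal preferred over up
    (gap in b) over left (gap in a); the end cell is the first strict
    maximum over last-row/last-column cells scanned in (i, j) order.
    Returns (score, columns, matches, (a0, a1), (b0, b1)) or None if the
    best alignment is empty.
    """
    la, lb = len(a), len(b)
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    P = [[0] * (lb + 1) for _ in range(la + 1)]  # 0 stop, 1 diag, 2 up, 3 left
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            ms = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
            best, ptr = H[i - 1][j - 1] + ms, 1
            if H[i - 1][j] - 1 > best:
                best, ptr = H[i - 1][j] - 1, 2
            if H[i][j - 1] - 1 > best:
                best, ptr = H[i][j - 1] - 1, 3
            H[i][j] = best
            P[i][j] = ptr
    best, bi, bj = None, -1, -1
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == la or j == lb:
                if best is None or H[i][j] > best:
                    best, bi, bj = H[i][j], i, j
    i, j = bi, bj
    columns = matches = 0
    while i > 0 and j > 0 and P[i][j] != 0:
        ptr = P[i][j]
        columns += 1
        if ptr == 1:
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            i, j = i - 1, j - 1
        elif ptr == 2:
            i -= 1
        else:
            j -= 1
    if columns == 0:
        return None
    return best, columns, matches, (i, bi), (j, bj)


def kmers(s: str, k: int) -> set[str]:
    return {s[i : i + k] for i in range(len(s) - k + 1) if "N" not in s[i : i + k]}


def naive_overlap_set(sequences, k, min_len, min_id):
    """All-pairs overlap enumeration restricted to pairs sharing an exact
    k-mer and passing the length/identity thresholds via full DP."""
    out = {}
    ksets = [kmers(s, k) for s in sequences]
    for i in range(len(sequences)):
        for j in range(i + 1, len(sequences)):
            if not (ksets[i] & ksets[j]):
                continue
            res = full_overlap_dp(sequences[i], sequences[j])
            if res is None:
                continue
            score, cols, matches, _, _ = res
            ident = 100.0 * matches / cols
            if cols >= min_len and ident >= min_id:
                out[(i, j)] = (cols, ident)
    return out


def edit_distance(a: str, b: str) -> int:
    """Global (NW) edit distance via edlib."""
    import edlib

    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def pileup_depth(genome_length: int, starts, lengths) -> np.ndarray:
    """Brute-force per-position read depth."""
    depth = np.zeros(genome_length, dtype=np.int64)
    for s, l in zip(starts, lengths):
        depth[s : s + l] += 1
    return depth


def check_matching_validity(level, params) -> None:
    """Matching is a valid, constrained-maximal matching of its level.

    Eligibility mirrors the contract: weight >= min_edge_weight and
    edge_density(u, v) > min_density.  After the final pass no eligible edge
    may remain with both endpoints unmatched.
    """
    G = level.graph
    M = level.matching
    nw, ew = level.node_weights, level.edge_weights
    seen = set()
    edge_w = {}
    for u, v, w in G.iter_edges():
        edge_w[(u, v)] = w
    for u, v in M.pairs:
        assert u != v
        assert u not in seen and v not in seen, "node matched twice"
        seen.update((u, v))
        key = (min(u, v), max(u, v))
        assert key in edge_w, f"matched pair {key} is not an edge"
    assert set(M.unmatched) == set(range(G.n)) - seen
    unmatched = set(M.unmatched)
    for (u, v), w in edge_w.items():
        if u in unmatched and v in unmatched:
            if w < params.min_edge_weight:
                continue
            s = nw[u] + nw[v]
            density = 2.0 * (ew[u] + ew[v] + w) / (s * (s - 1.0))
            assert density <= params.min_density, (
                f"eligible edge ({u},{v}) left with both endpoints unmatched"
            )


def check_hierarchy_invariants(hier, params) -> None:
    """Structural invariant suite over every level of a hierarchy."""
    n0 = hier.levels[0].graph.n
    from ovlcoarse.graph import total_edge_weight

    w0 = total_edge_weight(hier.levels[0].graph)
    prev_edges = None
    for i, lv in enumerate(hier.levels):
        G = lv.graph
        assert lv.node_weights.sum() == n0, "node conservation violated"
        assert int(lv.edge_weights.sum()) + total_edge_weight(G) == w0, (
            "weight conservation violated"
        )
        # structural: no self loops, no parallel edges, sorted edge sets
        for u in range(G.n):
            dsts, ws = G.neighbors(u)
            assert np.all(dsts != u), "self-loop"
            assert np.all(np.diff(ws) <= 0), "edge set not weight-sorted"
            seen_dsts = dsts.tolist()
            assert len(set(seen_dsts)) == len(seen_dsts), "parallel edge"
        if prev_edges is not None:
            assert G.m <= prev_edges, "edge count increased"
        prev_edges = G.m
        if lv.matching is not None:
            check_matching_validity(lv, params)
            nxt = hier.levels[i + 1]
            assert nxt.graph.n == G.n - len(lv.matching.pairs)
        if lv.node_map_inverse is not None:
            prev = hier.levels[i - 1]
            for z in range(G.n):
                u = int(lv.node_map_inverse[2 * z])
                v = int(lv.node_map_inverse[2 * z + 1])
                assert prev.node_map[u] == z
                if v >= 0:
                    assert prev.node_map[v] == z
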