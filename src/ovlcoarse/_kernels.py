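"""Numba hot loops: banded overlap DP, q-gram counting, HEM matching.

Sequences enter these kernels as uint8 code arrays (A=0, C=1, G=2, T=3,
N=4); N never matches anything, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

# traceback pointers
_STOP, _DIAG, _UP, _LEFT = 0, 1, 2, 3


@njit(cache=True)
def qgram_common_count(a, b, q, counts):
    """Multiset count of q-grams common to code arrays a and b.

    ``counts`` is a caller-provided int32 scratch array of size 5**q; only
    touched entries are reset, so repeated calls are cheap.
    """
    na = a.size - q + 1
    nb = b.size - q + 1
    if na <= 0 or nb <= 0:
        return 0
    hi_pow = 1
    for _ in range(q - 1):
        hi_pow *= 5
    code = 0
    for j in range(q):
        code = code * 5 + a[j]
    counts[code] += 1
    for i in range(1, na):
        code = (code - a[i - 1] * hi_pow) * 5 + a[i + q - 1]
        counts[code] += 1
    common = 0
    code = 0
    for j in range(q):
        code = code * 5 + b[j]
    if counts[code] > 0:
        common += 1
        counts[code] -= 1
    for i in range(1, nb):
        code = (code - b[i - 1] * hi_pow) * 5 + b[i + q - 1]
        if counts[code] > 0:
            common += 1
            counts[code] -= 1
    # reset touched entries
    code = 0
    for j in range(q):
        code = code * 5 + a[j]
    counts[code] = 0
    for i in range(1, na):
        code = (code - a[i - 1] * hi_pow) * 5 + a[i + q - 1]
        counts[code] = 0
    return common


@njit(cache=True)
def banded_align_core(a, b, diag, band):
    """Overlap alignment (free end gaps) within +/-band of ``diag``.

    Unit scoring: match +1, mismatch -1, gap -1.  ``diag`` is the b-offset
    minus a-offset of the seed.  Returns
    (ok, score, columns, matches, a_start, a_end, b_start, b_end).
    Ties prefer diagonal over up (gap in b) over left (gap in a); the end
    cell is the first maximum in (i, t) scan order — all deterministic.
    """
    la = a.size
    lb = b.size
    W = 2 * band + 1
    H = np.full((la + 1, W), NEG, dtype=np.int64)
    P = np.zeros((la + 1, W), dtype=np.uint8)
    for i in range(la + 1):
        base = i + diag - band
        for t in range(W):
            j = base + t
            if j < 0 or j > lb:
                continue
            if i == 0 or j == 0:
                H[i, t] = 0
                P[i, t] = _STOP
                continue
            ms = 1 if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else -1
            best = H[i - 1, t] + ms
            ptr = _DIAG
            if t + 1 < W and H[i - 1, t + 1] - 1 > best:
                best = H[i - 1, t + 1] - 1
                ptr = _UP
            if t - 1 >= 0 and H[i, t - 1] - 1 > best:
                best = H[i, t - 1] - 1
                ptr = _LEFT
            H[i, t] = best
            P[i, t] = ptr
    # best end: any in-band cell on the last row or last column
    best_score = NEG
    bi = -1
    bt = -1
    for i in range(la + 1):
        base = i + diag - band
        for t in range(W):
            j = base + t
            if j < 0 or j > lb:
                continue
            if i == la or j == lb:
                if H[i, t] > best_score:
                    best_score = H[i, t]
                    bi = i
                    bt = t
    if bi < 0:
        return False, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i = bi
    t = bt
    columns = 0
    matches = 0
    while True:
        j = i + diag - band + t
        if i == 0 or j == 0:
            break
        ptr = P[i, t]
        if ptr == _DIAG:
            columns += 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
        elif ptr == _UP:
            columns += 1
            i -= 1
            t += 1
        elif ptr == _LEFT:
            columns += 1
            t -= 1
        else:
            break
    a_start = i
    b_start = i + diag - band + t
    a_end = bi
    b_end = bi + diag - band + bt
    if columns == 0:
        return False, 0, 0, 0, 0, 0, 0, 0
    return True, best_score, columns, matches, a_start, a_end, b_start, b_end


@njit(cache=True)
def evaluate_candidates(
    qseq,
    reads_flat,
    read_starts,
    read_lens,
    cand_rid,
    cand_diag,
    q,
    band,
    min_len,
    min_id,
    counts,
):
    """q-gram filter + banded alignment for one query's candidate list.

    Returns per-candidate (score, columns, matches, accepted) arrays;
    score -1 marks candidates rejected before or during alignment.
    """
    nc = cand_rid.size
    out_score = np.full(nc, -1, dtype=np.int64)
    out_cols = np.zeros(nc, dtype=np.int64)
    out_match = np.zeros(nc, dtype=np.int64)
    accepted = np.zeros(nc, dtype=np.uint8)
    la = qseq.size
    for c in range(nc):
        r = cand_rid[c]
        d = cand_diag[c]
        b = reads_flat[read_starts[r] : read_starts[r] + read_lens[r]]
        lb = b.size
        a0 = -d if d < 0 else 0
        a1 = min(la, lb - d)
        w = a1 - a0
        if w <= 0:
            continue
        max_err = int(np.ceil((1.0 - min_id / 100.0) * w))
        t_min = w + 1 - q * (max_err + 1)
        if t_min > 0:
            b0 = d if d > 0 else 0
            common = qgram_common_count(qseq[a0:a1], b[b0 : b0 + w], q, counts)
            if common < t_min:
                continue
        ok, score, cols, matches, _, _, _, _ = banded_align_core(qseq, b, d, band)
        if not ok:
            continue
        out_score[c] = score
        out_cols[c] = cols
        out_match[c] = matches
        ident = 100.0 * matches / cols
        if cols >= min_len and ident >= min_id:
            accepted[c] = 1
    return out_score, out_cols, out_match, accepted


@njit(cache=True)
def hem_match_pass(order, offsets, dst, w, nw, ew, min_edge_weight, min_density, matched):
    """One matching sweep; mutates ``matched`` (partner id, -1 if unmatched).

    Neighbors are scanned in stored (descending-weight) order; the scan stops
    once the weight drops below the floor, while density failures merely skip
    the neighbor (density is not monotone in weight).
    """
    for oi in range(order.size):
        u = order[oi]
        if matched[u] >= 0:
            continue
        lo = offsets[u]
        hi = offsets[u + 1]
        for e in range(lo, hi):
            if w[e] < min_edge_weight:
                break
            v = dst[e]
            if matched[v] >= 0 or v == u:
                continue
            s = nw[u] + nw[v]
            density = 2.0 * (ew[u] + ew[v] + w[e]) / (s * (s - 1.0))
            if density > min_density:
                matched[u] = v
                matched[v] = u
                break
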