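"""Exact-match seeded read overlapper.

All reads are concatenated (sentinel-separated) into one string indexed by a
suffix array.  Each read in turn contributes its component k-mer seeds,
which are binary-searched in the suffix array; hits in other reads define
candidate pairs and seed diagonals.  Candidates pass through a q-gram filter
and are then extended by a banded overlap alignment (free end gaps) around
the seed diagonal.  An overlap is accepted when the alignment length and
percent identity meet the user thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._kernels import banded_align_core, evaluate_candidates, qgram_common_count
from .seqio import OverlapRecord, OverlapTable, ReadSet

SENTINEL = "$"

# suffix order follows ASCII: $ < A < C < G < N < T
_SA_RANK = np.zeros(256, dtype=np.uint8)
for _i, _c in enumerate("$ACGNT"):
    _SA_RANK[ord(_c)] = _i

# alignment codes: A C G T N -> 0..4 (N matches nothing)
_ALN_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ALN_CODE[ord(_c)] = _i


@dataclass
class OverlapParams:
    """Thresholds and seeding parameters for the overlapper.

    The experiments' own values for k, q, band and the acceptance thresholds
    are an engineering choice; all are exposed as flags.
    """

    k: int = 16
    q: int = 8
    band: int = 8
    min_overlap_length: int = 50
    min_identity: float = 90.0
    stride: int = 1  # seed every stride-th k-mer; 1 = all l-k+1 seeds

    def __post_init__(self) -> None:
        if not 1 <= self.q <= self.k:
            raise ValueError("require 1 <= q <= k")
        if self.band < 1:
            raise ValueError("band must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity is a percentage")


@dataclass(frozen=True)
class SeedHit:
    query_id: int
    ref_id: int
    query_offset: int
    ref_text_position: int
    diagonal: int  # ref_offset - query_offset


@dataclass
class SuffixArrayIndex:
    text: str
    sa: np.ndarray        # int64 suffix start positions, lexicographic order
    starts: np.ndarray    # int64 text start position of each read
    read_lengths: np.ndarray
    ranks: np.ndarray     # uint8 per-position character rank ($<A<C<G<N<T)

    @property
    def n_reads(self) -> int:
        return self.starts.size

    def pos_to_read(self, pos: int) -> Optional[tuple[int, int]]:
        """Invert concatenation: text position -> (read_id, offset), or None
        for sentinel positions."""
        rid = int(np.searchsorted(self.starts, pos, side="right")) - 1
        off = pos - int(self.starts[rid])
        if off >= int(self.read_lengths[rid]):
            return None
        return rid, off


def build_suffix_array(text: str) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy argsorts)."""
    if not text:
        raise ValueError("text must be non-empty")
    n = len(text)
    a = np.frombuffer(text.encode("ascii"), dtype=np.uint8)
    rank = np.unique(a, return_inverse=True)[1].astype(np.int64)
    shift = 1
    while True:
        second = np.zeros(n, dtype=np.int64)
        second[: n - shift] = rank[shift:] + 1
        key = rank * (n + 1) + second
        sa = np.argsort(key, kind="stable")
        sk = key[sa]
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[sa] = np.concatenate(
            ([0], np.cumsum(sk[1:] != sk[:-1]))
        )
        rank = new_rank
        if rank[sa[-1]] == n - 1:
            return sa.astype(np.int64)
        shift *= 2


def build_index(reads: ReadSet) -> SuffixArrayIndex:
    """Concatenate all reads (sentinel-terminated) and index the result."""
    if reads.n_reads < 1:
        raise ValueError("need at least one read")
    text = SENTINEL.join(reads.sequences) + SENTINEL
    # starts: read i begins at sum of (len+1) of previous reads
    lens = reads.lengths
    starts = np.zeros(reads.n_reads, dtype=np.int64)
    np.cumsum(lens[:-1] + 1, out=starts[1:])
    sa = build_suffix_array(text)
    ranks = _SA_RANK[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]
    return SuffixArrayIndex(
        text=text, sa=sa, starts=starts, read_lengths=lens, ranks=ranks
    )


def _window_codes(ranks: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-6 code and ACGT-validity of the k-window starting at each position.

    Codes are ordered consistently with suffix order, so ``codes[sa]`` is
    nondecreasing and supports binary search for exact k-mer intervals.
    Windows running past the end are padded with the sentinel rank (0).
    """
    n = ranks.size
    r = np.concatenate([ranks.astype(np.int64), np.zeros(k - 1, dtype=np.int64)])
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        cj = r[j : j + n]
        codes = codes * 6 + cj
        valid &= (cj != 0) & (cj != 4)  # no sentinel, no N
    return codes, valid


def kmer_code(kmer: str) -> int:
    """Base-6 suffix-order code of a k-mer (must be pure A/C/G/T)."""
    code = 0
    for c in kmer:
        rank = int(_SA_RANK[ord(c)])
        if rank in (0, 4) and c not in "ACGT":
            raise ValueError(f"k-mer contains non-ACGT character {c!r}")
        code = code * 6 + rank
    return code


def find_seed_hits(index: SuffixArrayIndex, query_id: int, k: int, stride: int = 1) -> list[SeedHit]:
    """All exact k-mer matches of the query's component seeds in other reads.

    Seeds containing N produce no hits; hits inside the query read itself are
    excluded.
    """
    l = int(index.read_lengths[query_id])
    if k > l:
        raise ValueError(f"k={k} exceeds query length {l}")
    codes, valid = _window_codes(index.ranks, k)
    codes_by_sa = codes[index.sa]
    tstart = int(index.starts[query_id])
    hits: list[SeedHit] = []
    for off in range(0, l - k + 1, stride):
        pos = tstart + off
        if not valid[pos]:
            continue
        code = codes[pos]
        lo = int(np.searchsorted(codes_by_sa, code, side="left"))
        hi = int(np.searchsorted(codes_by_sa, code, side="right"))
        for p in map(int, sorted(index.sa[lo:hi])):
            hit = index.pos_to_read(p)
            if hit is None:
                continue
            rid, roff = hit
            if rid == query_id:
                continue
            hits.append(
                SeedHit(
                    query_id=query_id,
                    ref_id=rid,
                    query_offset=off,
                    ref_text_position=p,
                    diagonal=roff - off,
                )
            )
    return hits


def max_errors_for(window_length: int, min_identity: float) -> int:
    """Edit-error budget implied by the identity threshold on a window."""
    return int(math.ceil((1.0 - min_identity / 100.0) * window_length))


def qgram_pass(a_window: str, b_window: str, q: int, max_errors: int) -> bool:
    """q-gram lemma filter: may the windows be within ``max_errors`` edits?

    Passes iff the number of common q-grams (multiset) reaches
    t = w + 1 - q*(max_errors + 1) with w the shorter window length; t <= 0
    always passes.  Never rejects a pair within the error budget.
    """
    w = min(len(a_window), len(b_window))
    t = w + 1 - q * (max_errors + 1)
    if t <= 0:
        return True
    a = _ALN_CODE[np.frombuffer(a_window.encode("ascii"), dtype=np.uint8)]
    b = _ALN_CODE[np.frombuffer(b_window.encode("ascii"), dtype=np.uint8)]
    counts = np.zeros(5**q, dtype=np.int32)
    return int(qgram_common_count(a, b, q, counts)) >= t


def banded_overlap_align(
    a: str, b: str, diagonal: int, band: int
) -> Optional[tuple[int, float, tuple[int, int], tuple[int, int]]]:
    """Banded overlap alignment of a vs b around the seed diagonal.

    Free end gaps (overlap-style), unit match/mismatch/indel scores.  With
    band >= max(|a|,|b|) and diagonal 0 this equals the unrestricted overlap
    alignment.  Returns (alignment_length, identity_percent, a_interval,
    b_interval) or None for a degenerate/empty overlap.
    """
    ac = _ALN_CODE[np.frombuffer(a.encode("ascii"), dtype=np.uint8)]
    bc = _ALN_CODE[np.frombuffer(b.encode("ascii"), dtype=np.uint8)]
    ok, _score, cols, matches, a0, a1, b0, b1 = banded_align_core(
        ac, bc, diagonal, band
    )
    if not ok:
        return None
    identity = 100.0 * matches / cols
    return cols, identity, (a0, a1), (b0, b1)


def _cluster_diagonals(
    rid: np.ndarray, diag: np.ndarray, count: np.ndarray, band: int
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-(ref, diagonal) seed hits into one candidate per diagonal
    cluster; the representative is the cluster's most-hit diagonal."""
    # rid-major, diag-minor sorted on input
    new = np.ones(rid.size, dtype=bool)
    if rid.size > 1:
        same_ref = rid[1:] == rid[:-1]
        close = (diag[1:] - diag[:-1]) <= band
        new[1:] = ~(same_ref & close)
    cluster = np.cumsum(new) - 1
    n_clusters = int(cluster[-1]) + 1 if rid.size else 0
    out_rid = np.empty(n_clusters, dtype=np.int64)
    out_diag = np.empty(n_clusters, dtype=np.int64)
    # pick, per cluster, the diagonal with the highest hit count (ties: smallest)
    order = np.lexsort((diag, -count, cluster))
    first = np.ones(order.size, dtype=bool)
    cl_sorted = cluster[order]
    first[1:] = cl_sorted[1:] != cl_sorted[:-1]
    sel = order[first]
    out_rid[cl_sorted[first]] = rid[sel]
    out_diag[cl_sorted[first]] = diag[sel]
    return out_rid, out_diag


def overlap_all(reads: ReadSet, params: OverlapParams) -> OverlapTable:
    """Detect all pairwise overlaps meeting the thresholds.

    Each unordered pair is evaluated once (from its lower-id member); when
    several seed-diagonal clusters produce alignments, the best (score, then
    length) is kept.  Deterministic for fixed input.
    """
    if reads.n_reads < 2:
        return OverlapTable(records=[])
    k, q, band = params.k, params.q, params.band
    index = build_index(reads)
    codes, valid = _window_codes(index.ranks, k)
    codes_by_sa = codes[index.sa]
    starts = index.starts
    lens = index.read_lengths
    max_len = int(lens.max())
    M = 2 * max_len + 1

    # flat alignment-code storage for all reads
    text_codes = _ALN_CODE[np.frombuffer(index.text.encode("ascii"), dtype=np.uint8)]
    counts_scratch = np.zeros(5**q, dtype=np.int32)

    records: list[OverlapRecord] = []
    for qid in range(reads.n_reads):
        l = int(lens[qid])
        if l < k:
            continue
        t0 = int(starts[qid])
        qpos = np.arange(t0, t0 + l - k + 1, params.stride)
        qv = valid[qpos]
        if not qv.any():
            continue
        qcodes = codes[qpos[qv]]
        qoffs = (qpos[qv] - t0).astype(np.int64)
        lo = np.searchsorted(codes_by_sa, qcodes, side="left")
        hi = np.searchsorted(codes_by_sa, qcodes, side="right")
        reps = hi - lo
        total = int(reps.sum())
        if total == 0:
            continue
        cum = np.cumsum(reps)
        flat = np.arange(total) - np.repeat(cum - reps, reps) + np.repeat(lo, reps)
        positions = index.sa[flat]
        qoff_per_hit = np.repeat(qoffs, reps)
        rid = np.searchsorted(starts, positions, side="right") - 1
        roff = positions - starts[rid]
        keep = rid > qid  # each unordered pair from its lower-id member
        if not keep.any():
            continue
        rid = rid[keep]
        diag = (roff - qoff_per_hit)[keep]
        key = rid * M + (diag + max_len)
        ukey, ucount = np.unique(key, return_counts=True)
        cand_rid, cand_diag = _cluster_diagonals(
            ukey // M, ukey % M - max_len, ucount, band
        )
        qseq = text_codes[t0 : t0 + l]
        score, cols, matches, accepted = evaluate_candidates(
            qseq,
            text_codes,
            starts,
            lens,
            cand_rid,
            cand_diag,
            q,
            band,
            params.min_overlap_length,
            float(params.min_identity),
            counts_scratch,
        )
        acc = accepted.astype(bool)
        if not acc.any():
            continue
        # best accepted alignment per ref: max (score, cols), ties by order
        order = np.lexsort((-cols[acc], -score[acc], cand_rid[acc]))
        rr = cand_rid[acc][order]
        first = np.ones(rr.size, dtype=bool)
        first[1:] = rr[1:] != rr[:-1]
        for j in np.flatnonzero(first):
            i = order[j]
            records.append(
                OverlapRecord(
                    query_id=qid,
                    ref_id=int(rr[j]),
                    alignment_length=int(cols[acc][i]),
                    identity=100.0 * float(matches[acc][i]) / float(cols[acc][i]),
                )
            )
    return OverlapTable(records=records)
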