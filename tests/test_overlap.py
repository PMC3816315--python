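from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovlcoarse.overlap import (
    OverlapParams,
    banded_overlap_align,
    build_index,
    build_suffix_array,
    find_seed_hits,
    max_errors_for,
    overlap_all,
    qgram_pass,
)
from ovlcoarse.seqio import ReadSet

from conftest import random_reads, tiled_reads
from oracles import edit_distance, full_overlap_dp, kmers, naive_overlap_set, naive_suffix_array


class TestSuffixArray:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("banana", [5, 3, 1, 0, 4, 2]),
            ("AAA", [2, 1, 0]),
            ("x", [0]),
        ],
    )
    def test_known_arrays(self, text, expected):
        assert build_suffix_array(text).tolist() == expected

    def test_matches_naive_sort_on_random_strings(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 400))
            s = "".join(rng.choice(list("ACGT$"), size=n))
            assert build_suffix_array(s).tolist() == naive_suffix_array(s)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_suffix_array("")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN$ab", min_size=1, max_size=200))
def test_suffix_array_matches_naive_property(s):
    assert build_suffix_array(s).tolist() == naive_suffix_array(s)


class TestIndex:
    def test_concatenation_and_boundaries(self):
        rs = ReadSet(sequences=["AC", "GT"], ids=["a", "b"])
        idx = build_index(rs)
        assert idx.text == "AC$GT$"
        assert idx.pos_to_read(3) == (1, 0)
        assert idx.pos_to_read(2) is None  # sentinel

    def test_single_read_offsets_are_identity(self):
        idx = build_index(ReadSet(sequences=["ACGT"], ids=["a"]))
        for p in range(4):
            assert idx.pos_to_read(p) == (0, p)

    def test_every_position_roundtrips(self, rng):
        rs = random_reads(rng, n=50)
        idx = build_index(rs)
        pos = 0
        for rid, seq in enumerate(rs.sequences):
            for off in range(len(seq)):
                assert idx.pos_to_read(pos) == (rid, off)
                pos += 1
            assert idx.pos_to_read(pos) is None
            pos += 1


class TestSeedHits:
    def brute_hits(self, rs, qid, k):
        """Brute-force substring scan over all other reads."""
        out = set()
        q = rs.sequences[qid]
        for off in range(len(q) - k + 1):
            kmer = q[off : off + k]
            if "N" in kmer:
                continue
            for rid, ref in enumerate(rs.sequences):
                if rid == qid:
                    continue
                start = 0
                while True:
                    p = ref.find(kmer, start)
                    if p < 0:
                        break
                    out.add((rid, off, p))
                    start = p + 1
        return out

    def test_verbatim_query_found_with_correct_diagonal(self):
        rs = ReadSet(
            sequences=["CCCCACGTACGTTTTT", "ACGTACGT"], ids=["ref", "q"]
        )
        hits = find_seed_hits(build_index(rs), 1, 8)
        assert any(h.ref_id == 0 and h.diagonal == 4 for h in hits)

    def test_all_n_query_yields_no_hits(self):
        rs = ReadSet(sequences=["N" * 20, "ACGTACGTACGTACGTACGT"], ids=["q", "r"])
        assert find_seed_hits(build_index(rs), 0, 8) == []

    def test_identical_reads_hit_diagonal_zero_for_every_seed(self):
        s = "ACGGTTACCAGT"
        rs = ReadSet(sequences=[s, s], ids=["a", "b"])
        hits = find_seed_hits(build_index(rs), 0, 4)
        diag0 = [h for h in hits if h.diagonal == 0]
        assert len(diag0) == len(s) - 4 + 1

    def test_matches_brute_force_scan(self, rng):
        rs = random_reads(rng, n=12, min_len=20, max_len=40)
        # plant a shared motif so hits exist
        motif = "ACGTTGCAAC"
        seqs = list(rs.sequences)
        seqs[3] = seqs[3][:5] + motif + seqs[3][15:]
        seqs[7] = seqs[7][:12] + motif + seqs[7][22:]
        rs = ReadSet(sequences=seqs, ids=rs.ids)
        idx = build_index(rs)
        for qid in range(rs.n_reads):
            got = {
                (h.ref_id, h.query_offset, idx.pos_to_read(h.ref_text_position)[1])
                for h in find_seed_hits(idx, qid, 8)
            }
            assert got == self.brute_hits(rs, qid, 8)


class TestQgram:
    def test_identical_windows_pass(self):
        assert qgram_pass("ACGTACGTACGT", "ACGTACGTACGT", 4, 0)

    def test_disjoint_alphabets_fail(self):
        assert not qgram_pass("A" * 30, "C" * 30, 4, 1)

    def test_tiny_windows_always_pass(self):
        # t <= 0: the lemma gives no constraint
        assert qgram_pass("ACG", "TTT", 4, 0)

    def test_never_rejects_within_edit_budget(self, rng):
        """q-gram lemma soundness against a DP edit-distance oracle."""
        bases = list("ACGT")
        for _ in range(300):
            n = int(rng.integers(30, 120))
            a = "".join(rng.choice(bases, size=n))
            b = list(a)
            n_edits = int(rng.integers(0, 6))
            for _ in range(n_edits):
                op = rng.integers(0, 3)
                pos = int(rng.integers(0, len(b)))
                if op == 0:
                    b[pos] = str(rng.choice(bases))
                elif op == 1 and len(b) > 1:
                    del b[pos]
                else:
                    b.insert(pos, str(rng.choice(bases)))
            b = "".join(b)
            e = edit_distance(a, b)
            assert e <= n_edits
            assert qgram_pass(a, b, 8, e)


class TestBandedAlign:
    def test_identical_sequences_full_identity(self):
        res = banded_overlap_align("ACGTACGTAA", "ACGTACGTAA", 0, 4)
        cols, ident, (a0, a1), (b0, b1) = res
        assert cols == 10 and ident == 100.0
        assert (a0, a1) == (0, 10) and (b0, b1) == (0, 10)

    def test_single_mismatch_identity(self):
        cols, ident, _, _ = banded_overlap_align("ACGT", "ACGA", 0, 4)
        assert cols == 4
        assert ident == 75.0

    def test_suffix_prefix_overlap(self):
        # last 6 of a == first 6 of b
        a, b = "TTTTACGACG", "ACGACGCCCC"
        cols, ident, (a0, a1), (b0, b1) = banded_overlap_align(a, b, -4, 3)
        assert cols == 6 and ident == 100.0
        assert (a0, a1) == (4, 10)
        assert (b0, b1) == (0, 6)

    def test_full_band_equals_quadratic_dp(self, rng):
        """With the band covering the whole matrix the banded DP reproduces
        the unrestricted overlap alignment."""
        bases = list("ACGT")
        for trial in range(60):
            la = int(rng.integers(10, 80))
            lb = int(rng.integers(10, 80))
            if trial % 2 == 0:
                a = "".join(rng.choice(bases, size=la))
                b = "".join(rng.choice(bases, size=lb))
            else:
                # genuinely overlapping pair with substitutions
                core = "".join(rng.choice(bases, size=60))
                a = "".join(rng.choice(bases, size=20)) + core[:40]
                b = core[:40] + "".join(rng.choice(bases, size=20))
                b = "".join(
                    c if rng.random() > 0.03 else str(rng.choice(bases)) for c in b
                )
            band = max(len(a), len(b))
            got = banded_overlap_align(a, b, 0, band)
            exp = full_overlap_dp(a, b)
            if exp is None:
                assert got is None
                continue
            score, cols, matches, a_iv, b_iv = exp
            assert got is not None
            g_cols, g_ident, g_a, g_b = got
            assert g_cols == cols
            assert g_ident == pytest.approx(100.0 * matches / cols)
            assert g_a == a_iv and g_b == b_iv

    def test_off_band_overlap_rejected_or_worse(self):
        # true overlap on diagonal -4; band centered far away cannot see it
        a, b = "TTTTACGACG", "ACGACGCCCC"
        narrow = banded_overlap_align(a, b, 4, 2)
        full = banded_overlap_align(a, b, -4, 3)
        assert full[0] == 6
        assert narrow is None or narrow[1] < 100.0 or narrow[0] < 6


class TestOverlapAll:
    def test_exact_suffix_prefix_pair(self, rng):
        bases = list("ACGT")
        genome = "".join(rng.choice(bases, size=160))
        a, b = genome[:100], genome[40:140]  # 60 bp suffix-prefix overlap
        rs = ReadSet(sequences=[a, b], ids=["a", "b"])
        params = OverlapParams(k=16, min_overlap_length=50, min_identity=90)
        table = overlap_all(rs, params)
        assert len(table) == 1
        rec = table.records[0]
        assert rec.alignment_length == 60
        assert rec.identity == 100.0

    def test_unrelated_reads_yield_nothing(self, rng):
        rs = random_reads(rng, n=2, min_len=100, max_len=100)
        assert len(overlap_all(rs, OverlapParams())) == 0

    def test_matches_naive_all_pairs_dp(self, rng):
        """Tiled-genome overlap set equals the brute-force enumeration."""
        rs = tiled_reads(rng, genome_length=2000, n_reads=50)
        params = OverlapParams(k=16, min_overlap_length=50, min_identity=90)
        table = overlap_all(rs, params)
        got = {
            (min(r.query_id, r.ref_id), max(r.query_id, r.ref_id)): (
                r.alignment_length,
                round(r.identity, 6),
            )
            for r in table
        }
        exp = {
            pair: (cols, round(ident, 6))
            for pair, (cols, ident) in naive_overlap_set(
                rs.sequences, 16, 50, 90.0
            ).items()
        }
        assert got == exp

    def test_symmetry_under_read_order_reversal(self, rng):
        rs = tiled_reads(rng, genome_length=1200, n_reads=25)
        params = OverlapParams()
        fwd = overlap_all(rs, params)
        rev = ReadSet(sequences=rs.sequences[::-1], ids=rs.ids[::-1])
        bwd = overlap_all(rev, params)
        n = rs.n_reads

        def norm(table, flip):
            out = set()
            for r in table:
                q, f = (n - 1 - r.query_id, n - 1 - r.ref_id) if flip else (r.query_id, r.ref_id)
                out.add((min(q, f), max(q, f), r.alignment_length))
            return out

        assert norm(fwd, False) == norm(bwd, True)

    def test_max_errors_derivation(self):
        assert max_errors_for(100, 90.0) == 10
        assert max_errors_for(55, 90.0) == 6  # ceil(5.5)
        assert max_errors_for(60, 100.0) == 0
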