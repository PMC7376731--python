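"""Reference k-mer indexes: enumeration, sampling schemes, occurrence
filtering and seed lookup."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from seedbridge import (
    PositionedKmer,
    Sequence,
    build_index,
    enumerate_kmers,
    load_index,
    lookup_seeds,
    sample_mstep,
    save_index,
    select_minimizers,
)
from seedbridge.indexing import apply_occurrence_filter, hash_order

dna = st.text(alphabet="ACGT", min_size=0, max_size=80).map(lambda s: Sequence("w", s))
dna_nonempty = st.text(alphabet="ACGT", min_size=12, max_size=300).map(lambda s: Sequence("w", s))


class TestEnumerateKmers:
    def test_direct_enumeration(self):
        kmers = enumerate_kmers(Sequence("w", "ACGTAC"), 3)
        assert kmers == [
            PositionedKmer(0, "ACG"),
            PositionedKmer(1, "CGT"),
            PositionedKmer(2, "GTA"),
            PositionedKmer(3, "TAC"),
        ]

    def test_single_window_and_short_word(self):
        assert enumerate_kmers(Sequence("w", "ACG"), 3) == [PositionedKmer(0, "ACG")]
        assert enumerate_kmers(Sequence("w", "AC"), 3) == []

    @pytest.mark.parametrize(
        "chars,expected_positions",
        [("ACNGT", []), ("ACNGTA", [3]), ("NACGTN", [1, 2])],
    )
    def test_windows_containing_ambiguity_are_omitted(self, chars, expected_positions):
        kmers = enumerate_kmers(Sequence("w", chars), 3)
        assert [km.x for km in kmers] == expected_positions
        for km in kmers:
            assert km.word == chars[km.x : km.x + 3]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            enumerate_kmers(Sequence("w", "ACGT"), 0)


class TestSampleMstep:
    def test_every_second_kmer(self):
        kmers = enumerate_kmers(Sequence("w", "ACGTAC"), 3)  # positions 0..3
        assert [km.x for km in sample_mstep(kmers, 2)] == [0, 2]

    def test_step_one_is_identity(self):
        kmers = enumerate_kmers(Sequence("w", "ACGTACGT"), 3)
        assert sample_mstep(kmers, 1) == kmers

    def test_no_multiples(self):
        kmers = [PositionedKmer(x, "AAA") for x in (1, 3, 5)]
        assert sample_mstep(kmers, 2) == []

    @given(dna_nonempty, st.integers(1, 5), st.integers(2, 5))
    def test_residue_classes_partition_the_full_index(self, W, k, m):
        """The full k-mer list is the disjoint union over shifts of the
        m-step samples of each residue class."""
        kmers = enumerate_kmers(W, k)
        sampled = sample_mstep(kmers, m)
        assert set(sampled) <= set(kmers)
        by_residue = [[km for km in kmers if km.x % m == r] for r in range(m)]
        assert sorted(sum(by_residue, []), key=lambda km: km.x) == kmers
        assert by_residue[0] == sampled


class TestSelectMinimizers:
    def test_window_of_one_selects_everything(self):
        W = Sequence("w", "ACGTACGT")
        assert select_minimizers(W, 1, 3) == enumerate_kmers(W, 3)

    def test_lexicographic_hand_example(self):
        # windows {ACG,CGT} -> ACG and {CGT,GTA} -> CGT
        sel = select_minimizers(Sequence("w", "ACGTA"), 2, 3, order="lex")
        assert [km.x for km in sel] == [0, 1]

    def test_too_short_word(self):
        assert select_minimizers(Sequence("w", "ACG"), 3, 3) == []

    def test_ties_select_all_positions(self):
        # AAAA k-mers tie everywhere; every position must be selected to keep
        # the shared-minimizer guarantee
        sel = select_minimizers(Sequence("w", "AAAAAA"), 2, 3, order="lex")
        assert [km.x for km in sel] == [0, 1, 2, 3]

    @given(dna_nonempty, st.integers(1, 6), st.integers(2, 6))
    def test_adjacent_gap_and_covering_property(self, W, w, k):
        sel = select_minimizers(W, w, k)
        positions = [km.x for km in sel]
        assert positions == sorted(set(positions))
        for a, b in zip(positions, positions[1:]):
            assert b - a <= w
        # covering: every window of w consecutive k-mer starts holds a pick
        n_pos = len(W) - k + 1
        if n_pos >= w:
            pos_set = set(positions)
            for start in range(n_pos - w + 1):
                assert any(p in pos_set for p in range(start, start + w))

    @given(st.text(alphabet="ACGT", min_size=20, max_size=60))
    def test_shared_substring_shares_a_minimizer(self, shared):
        """Two words sharing a substring of length >= w + k - 1 share a
        selected k-mer at the homologous offset."""
        w, k = 4, 5
        if len(shared) < w + k - 1:
            return
        A = Sequence("a", "ACACAC" + shared)
        B = Sequence("b", shared + "GTGTGT")
        sel_a = {(km.x - 6, km.word) for km in select_minimizers(A, w, k)}
        sel_b = {(km.x, km.word) for km in select_minimizers(B, w, k)}
        # a full window of w k-mer starts fits inside the shared substring,
        # and a window minimum depends only on the window's own k-mers, so
        # both words select the same position inside that window
        common_span = {(x, wd) for x, wd in sel_b if 0 <= x and x + k <= len(shared)}
        assert any((x, wd) in sel_a for x, wd in common_span)


class TestBuildIndexAndFilter:
    def test_occurrence_filter_is_strict_inequality(self):
        # AAA occurs 2001 times, CCC exactly 2000; with threshold 2000 the
        # filter must purge AAA (strictly more) and keep CCC (equal)
        R = Sequence("r", "AAAT" * 2001 + "CCCT" * 2000)
        idx = build_index(R, k=3, scheme="full")
        assert len(idx.buckets["AAA"]) == 2001 and len(idx.buckets["CCC"]) == 2000
        apply_occurrence_filter(idx, 2000)
        assert "AAA" not in idx.buckets
        assert "AAA" in idx.purged_words
        assert len(idx.buckets["CCC"]) == 2000 and "CCC" not in idx.purged_words

    def test_no_threshold_means_no_purging(self):
        idx = build_index(Sequence("r", "AAAAAAAA"), k=3, scheme="full")
        assert idx.purged_words == set()

    def test_repetitive_kmers_purged_renders_mem_undiscoverable(self):
        """A unique 6-mer whose constituent 3-mers are each frequent loses
        all its hash-table buckets to the occurrence filter, so the seed
        lookup for it comes back empty."""
        R = Sequence("r", "CTCAGACTCAGACTCAGA")
        idx = build_index(R, k=3, scheme="minimizer", m_or_w=1, occ_threshold=2)
        assert idx.purged_words == {"CTC", "TCA", "CAG", "AGA"}
        assert lookup_seeds(Sequence("q", "CTCAGA"), idx) == []

    def test_parameter_errors(self):
        R = Sequence("r", "ACGTACGT")
        with pytest.raises(ValueError):
            build_index(R, k=0)
        with pytest.raises(ValueError):
            build_index(R, k=3, scheme="m-step", m_or_w=0)
        with pytest.raises(ValueError):
            build_index(R, k=3, scheme="minimizer")

    @given(dna_nonempty, st.integers(1, 4))
    def test_raising_threshold_is_monotone(self, R, k):
        lo = build_index(R, k=k, scheme="full", occ_threshold=2)
        hi = build_index(R, k=k, scheme="full", occ_threshold=4)
        assert hi.purged_words <= lo.purged_words
        for word, positions in lo.buckets.items():
            assert hi.buckets[word] == positions


class TestLookupSeeds:
    @given(dna_nonempty, st.text(alphabet="ACGT", min_size=5, max_size=60), st.integers(2, 5))
    def test_full_index_equals_bruteforce_cross_product(self, R, q_chars, k):
        Q = Sequence("q", q_chars)
        idx = build_index(R, k=k, scheme="full")
        got = set(lookup_seeds(Q, idx))
        expected = {
            (q, r)
            for q in range(len(Q) - k + 1)
            for r in range(len(R) - k + 1)
            if Q[q : q + k] == R[r : r + k] and "N" not in Q[q : q + k]
        }
        assert {(s.q, s.r) for s in got} == expected
        assert all(s.l == k for s in got)

    def test_query_with_absent_kmers(self):
        idx = build_index(Sequence("r", "ACGTACGT"), k=3, scheme="full")
        assert lookup_seeds(Sequence("q", "GGG"), idx) == []

    def test_repeat_reference_yields_both_occurrences(self):
        idx = build_index(Sequence("r", "ACGACG"), k=3, scheme="full")
        seeds = set(lookup_seeds(Sequence("q", "ACG"), idx))
        assert {(s.q, s.r) for s in seeds} == {(0, 0), (0, 3)}

    def test_query_side_is_never_sampled_by_default(self):
        R = Sequence("r", "TTTTACGTTTTT")
        Q = Sequence("q", "AACGTA")
        idx = build_index(R, k=3, scheme="m-step", m_or_w=4)
        # reference positions sampled: 0, 4, 8 -> TTT, ACG, TTT
        assert all(x % 4 == 0 for positions in idx.buckets.values() for x in positions)
        # the query k-mer ACG sits at q=1, an odd position: still looked up
        seeds = lookup_seeds(Q, idx)
        assert any(s.q == 1 and s.r == 4 for s in seeds)

    def test_query_minimizer_mode_restricts_query_side(self):
        R = Sequence("r", "ACGTACGTAA")
        Q = Sequence("q", "ACGTACGTAA")
        idx = build_index(R, k=3, scheme="minimizer", m_or_w=3)
        dense = lookup_seeds(Q, idx)
        sketched = lookup_seeds(Q, idx, query_minimizers=True)
        assert set(sketched) <= set(dense)


def test_index_persistence_roundtrip(tmp_path):
    R = Sequence("chrM", "ACGTACGTACGTTTTTTTTT")
    idx = build_index(R, k=3, scheme="minimizer", m_or_w=2, occ_threshold=3)
    p = tmp_path / "idx.jsonl"
    save_index(idx, p)
    loaded = load_index(p)
    assert loaded == idx


def test_hash_order_is_deterministic_and_total():
    words = ["ACG", "CGT", "GTA", "TAC", "AAA"]
    keys = [hash_order(w) for w in words]
    assert len(set(keys)) == len(words)
    assert keys == [hash_order(w) for w in words]
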