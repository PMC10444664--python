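"""Unit tests for seed chaining and identity estimation at fixed k."""

import pytest

from seedchain.chain import (
    DUMMY_SEED,
    ChainResult,
    GapAccount,
    Seed,
    SequenceRecord,
    account_gaps,
    chain_seeds,
    estimate_identity,
    extend_seed,
    index_kmers,
    next_seed,
)


class TestSequenceRecord:
    def test_lowercase_is_canonicalised(self):
        assert SequenceRecord("s", "acgtn").seq == "ACGTN"

    @pytest.mark.parametrize(
        "id_, seq", [("", "ACGT"), ("s", ""), ("s", "ACGU"), ("s", "ACG T")]
    )
    def test_invalid_records_rejected(self, id_, seq):
        with pytest.raises(ValueError):
            SequenceRecord(id_, seq)


class TestIndexKmers:
    def test_single_kmer(self):
        assert index_kmers("GCG", 3) == {"GCG": [0]}

    def test_all_3mers_enumerated(self):
        assert index_kmers("GCGGATTGAG", 3) == {
            "GCG": [0],
            "CGG": [1],
            "GGA": [2],
            "GAT": [3],
            "ATT": [4],
            "TTG": [5],
            "TGA": [6],
            "GAG": [7],
        }

    def test_kmers_with_n_are_excluded(self):
        assert index_kmers("ACNGT", 3) == {}

    def test_k_longer_than_sequence_gives_empty_map(self):
        assert index_kmers("ACG", 5) == {}

    def test_repeated_kmer_positions_sorted(self):
        assert index_kmers("AAAA", 2) == {"AA": [0, 1, 2]}


class TestExtendSeed:
    def test_extends_along_shared_run(self, worked_pair_a):
        a, b = worked_pair_a
        assert extend_seed(Seed(4, 3), a, b, 3) == Seed(5, 4)

    def test_homopolymer(self):
        assert extend_seed(Seed(0, 0), "AAAA", "AAAA", 3) == Seed(1, 1)

    def test_mismatch_blocks_extension(self, worked_pair_b):
        a, b = worked_pair_b
        assert extend_seed(Seed(5, 4), a, b, 3) is None

    def test_out_of_range_blocks_extension(self):
        assert extend_seed(Seed(1, 1), "AAAA", "AAAA", 3) is None


class TestNextSeed:
    def _idx(self, a, b, k):
        return index_kmers(a, k), index_kmers(b, k)

    def test_second_candidate_wins_on_smaller_shift(self, worked_pair_b):
        # Step-1 candidate (3, 6) has distance difference 3; Step-2
        # candidate (4, 3) has 1, so Step 3 picks the latter.
        a, b = worked_pair_b
        idx_i, idx_j = self._idx(a, b, 3)
        assert next_seed(Seed(0, 0), a, b, 3, idx_i, idx_j) == Seed(4, 3)

    def test_identical_sequences_start_at_origin(self):
        a = b = "ACGTACGT"
        idx_i, idx_j = self._idx(a, b, 3)
        assert next_seed(DUMMY_SEED, a, b, 3, idx_i, idx_j) == Seed(0, 0)

    def test_disjoint_kmer_sets_give_no_seed(self):
        a, b = "AAAA", "TTTT"
        idx_i, idx_j = self._idx(a, b, 2)
        assert next_seed(DUMMY_SEED, a, b, 2, idx_i, idx_j) is None


class TestChainSeeds:
    def test_worked_chain_of_four_seeds(self, worked_pair_a):
        a, b = worked_pair_a
        result = chain_seeds(a, b, 3)
        assert [(s.i, s.j) for s in result.seeds] == [(0, 0), (4, 3), (5, 4), (6, 5)]
        assert result.t == 4

    def test_worked_chain_through_step_two_candidate(self, worked_pair_b):
        a, b = worked_pair_b
        result = chain_seeds(a, b, 3)
        assert [(s.i, s.j) for s in result.seeds] == [(0, 0), (4, 3), (5, 4)]
        assert result.t == 3

    @pytest.mark.parametrize("k", [1, 3, 8, 12])
    def test_identical_sequences_full_seed_count(self, k):
        s = "ACGTAGCTAGCA"
        result = chain_seeds(s, s, k)
        assert result.t == len(s) - k + 1
        assert result.identity == 1.0

    def test_k_out_of_range_raises(self):
        with pytest.raises(ValueError):
            chain_seeds("ACGT", "ACGT", 5)

    def test_every_seed_is_a_true_kmer_match(self, worked_pair_b):
        a, b = worked_pair_b
        for k in (2, 3, 4):
            for s in chain_seeds(a, b, k).seeds:
                assert a[s.i : s.i + k] == b[s.j : s.j + k]


class TestAccountGaps:
    def test_internal_gap_and_unequal_tails(self):
        acc = account_gaps([Seed(0, 0), Seed(4, 3), Seed(5, 4)], 10, 10, 3)
        assert acc == GapAccount(subs=2, dels=1, ins=1)

    def test_identical_coverage_is_free(self):
        seeds = [Seed(i, i) for i in range(6)]
        assert account_gaps(seeds, 8, 8, 3) == GapAccount(0, 0, 0)

    def test_empty_chain_charges_everything(self):
        assert account_gaps([], 5, 7, 3) == GapAccount(subs=5, dels=0, ins=2)

    def test_leading_gap_measured_from_origin(self):
        # first seed away from (0, 0): the lead-in counts like any gap
        acc = account_gaps([Seed(2, 3)], 5, 6, 3)
        assert acc == GapAccount(subs=2, dels=0, ins=1)

    def test_decreasing_seeds_rejected(self):
        with pytest.raises(ValueError):
            account_gaps([Seed(4, 4), Seed(2, 6)], 10, 10, 3)
        with pytest.raises(ValueError):
            account_gaps([Seed(4, 4), Seed(5, 4)], 10, 10, 3)

    def test_overlapping_offdiagonal_seeds_charge_the_shift(self):
        # windows overlap but the diagonal moves by one: one insertion
        acc = account_gaps([Seed(0, 0), Seed(2, 3)], 5, 6, 3)
        assert acc.ins - acc.dels == 1
        assert acc.subs == 0


class TestEstimateIdentity:
    def test_seven_elevenths(self):
        assert estimate_identity(GapAccount(2, 1, 1), 10) == pytest.approx(7 / 11)

    def test_six_thirteenths(self):
        assert estimate_identity(GapAccount(4, 0, 3), 10) == pytest.approx(6 / 13)

    def test_identical(self):
        assert estimate_identity(GapAccount(0, 0, 0), 10) == 1.0

    def test_inconsistent_account_raises(self):
        with pytest.raises(ValueError):
            estimate_identity(GapAccount(8, 5, 0), 10)

    def test_zero_identity_for_fully_divergent(self):
        assert estimate_identity(GapAccount(5, 0, 2), 5) == 0.0


def test_chain_result_reports_estimated_identity(worked_pair_b):
    a, b = worked_pair_b
    result = chain_seeds(a, b, 3)
    assert isinstance(result, ChainResult)
    assert result.identity == pytest.approx(7 / 11)
    assert result.account == GapAccount(2, 1, 1)
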