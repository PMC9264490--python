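"""k-mer hashing, bit-vector and LIS scores, and the gap-variance statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denovotx.config import RunConfig
from denovotx.io import reverse_complement
from denovotx.similarity import (
    Triplet,
    bitvec_score,
    build_kmer_vector,
    build_triplets,
    compare_reads,
    covered_bases,
    gap_variance,
    hash_kmer,
    kmer_hashes,
    lis_chain,
    lis_similarity,
)

from .oracles import brute_force_lis_length, gap_variance_oracle


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestHash:
    @pytest.mark.parametrize(
        "kmer,expected",
        [("A", 0), ("C", 1), ("G", 2), ("T", 3), ("AAA", 0), ("ACG", 6), ("TT", 15)],
    )
    def test_base4_encoding(self, kmer, expected):
        assert hash_kmer(kmer) == expected

    def test_rejects_ambiguity(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            hash_kmer("ACN")

    def test_injective_and_matches_rolling(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 100)
        k = 5
        rolled = kmer_hashes(seq, k)
        direct = [hash_kmer(seq[i : i + k]) for i in range(len(seq) - k + 1)]
        assert rolled.tolist() == direct


class TestKmerVector:
    def test_enumerated_distinct_kmers(self, read_factory):
        # ACGTACGT with k=6: ACGTAC, CGTACG, GTACGT
        v = build_kmer_vector("ACGTACGT", 6)
        assert v.n_kmers == 3

    def test_homopolymer_single_bit(self):
        assert build_kmer_vector("AAAAAAAA", 6).n_kmers == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_vector("ACG", 6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_popcount_bounded_by_positions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 80))
        v = build_kmer_vector(random_seq(rng, n), 6)
        assert 1 <= v.n_kmers <= n - 6 + 1


class TestBitvecScore:
    def test_identical_reads(self):
        v = build_kmer_vector("ACGTACGTTT", 6)
        assert bitvec_score(v, v) == 1.0

    def test_disjoint_kmer_sets(self):
        v1 = build_kmer_vector("A" * 20, 6)
        v2 = build_kmer_vector("C" * 20, 6)
        assert bitvec_score(v1, v2) == 0.0

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError, match="k mismatch"):
            bitvec_score(build_kmer_vector("ACGTACGT", 6), build_kmer_vector("ACGTACGT", 7))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = random_seq(rng, 200), random_seq(rng, 200)
        k = 6
        set1 = {s1[i : i + k] for i in range(len(s1) - k + 1)}
        set2 = {s2[i : i + k] for i in range(len(s2) - k + 1)}
        expected = len(set1 & set2) / max(len(set1), len(set2))
        got = bitvec_score(build_kmer_vector(s1, k), build_kmer_vector(s2, k))
        assert got == pytest.approx(expected)
        # symmetry
        assert got == bitvec_score(build_kmer_vector(s2, k), build_kmer_vector(s1, k))


def triplets_from_p2(p2_values):
    return [Triplet(0, i, p2) for i, p2 in enumerate(p2_values)]


class TestLisChain:
    def test_known_small_instance(self):
        # p2 = (3,1,2,4): longest strictly increasing subsequence is (1,2,4)
        chain = lis_chain(triplets_from_p2([3, 1, 2, 4]))
        assert [t.p2 for t in chain] == [1, 2, 4]

    def test_empty(self):
        assert lis_chain([]) == []

    def test_identical_reads_full_chain(self):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 120)
        triplets = build_triplets(seq, seq, 10)
        chain = lis_chain(triplets)
        # every shared position chains (repeated k-mers cannot double-chain)
        assert [t.p1 for t in chain] == list(range(len(seq) - 10 + 1))

    def test_lexicographic_tie_break(self):
        # two equally long chains; the (p1, p2)-smallest must win
        triplets = sorted(
            [Triplet(0, 0, 5), Triplet(0, 0, 1), Triplet(0, 1, 6), Triplet(0, 1, 2)],
            key=lambda t: (t.p1, t.p2),
        )
        chain = lis_chain(triplets)
        assert [(t.p1, t.p2) for t in chain] == [(0, 1), (1, 2)]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_medium(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 13))
        triplets = sorted(
            (Triplet(0, int(rng.integers(0, 10)), int(rng.integers(0, 10)))
             for _ in range(n)),
            key=lambda t: (t.p1, t.p2),
        )
        assert len(lis_chain(triplets)) == brute_force_lis_length(triplets)


class TestLisSimilarity:
    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(7)
        seq = random_seq(rng, 150)
        rep = lis_similarity(seq, seq, 10)
        assert rep.lis_score == pytest.approx(1.0)

    def test_no_shared_kmers(self):
        rep = lis_similarity("A" * 50, "C" * 50, 10)
        assert rep.lis_score == 0.0
        assert rep.chain == []

    def test_truncated_copy_fully_covered(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 200)
        rep = lis_similarity(seq, seq[:100], 10)
        assert rep.lis_score == pytest.approx(1.0)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(9)
        base = random_seq(rng, 180)
        other = base[:90] + random_seq(rng, 60)
        a = lis_similarity(base, other, 10).lis_score
        b = lis_similarity(other, base, 10).lis_score
        assert a == pytest.approx(b)


class TestGapVariance:
    def test_identical_reads_zero(self):
        rng = np.random.default_rng(10)
        seq = random_seq(rng, 100)
        rep = lis_similarity(seq, seq, 10)
        assert gap_variance(rep.chain) == 0.0

    def test_two_member_chain_zero(self):
        chain = [Triplet(0, 0, 0), Triplet(0, 50, 10)]
        assert gap_variance(chain) == 0.0

    def test_single_exon_jump_matches_hand_computation(self):
        # 20 zero-difference gaps plus one 60-nt jump
        chain = [Triplet(0, 10 * i, 10 * i) for i in range(11)]
        chain += [Triplet(0, 10 * i + 60, 10 * i) for i in range(11, 22)]
        assert gap_variance(chain) == pytest.approx(gap_variance_oracle(chain))
        # one d=60 among 21 gaps: var = 60^2 * (21-1) / 21^2
        assert gap_variance(chain) == pytest.approx(60**2 * 20 / 21**2)

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_p2_shift(self, offset):
        chain = [Triplet(0, p, p + (3 if p > 40 else 0)) for p in range(0, 80, 7)]
        shifted = [Triplet(t.s, t.p1, t.p2 + offset) for t in chain]
        assert gap_variance(shifted) == pytest.approx(gap_variance(chain))

    def test_substitution_only_reads_have_zero_variance(self):
        from denovotx.simulate import simulate_read

        rng = np.random.default_rng(11)
        template = random_seq(rng, 400)
        for seed in range(5):
            r1 = simulate_read(template, 0.05, 0.0, 0.0, None, seed, "a")
            r2 = simulate_read(template, 0.05, 0.0, 0.0, None, seed + 100, "b")
            rep = lis_similarity(r1.seq, r2.seq, 11)
            assert gap_variance(rep.chain) == 0.0


class TestCompareReads:
    def test_rna_mode_misses_reverse_complement(self, read_factory):
        rng = np.random.default_rng(12)
        seq = random_seq(rng, 200)
        cfg = RunConfig(rna_mode=True)
        rep = compare_reads(
            read_factory("a", seq), read_factory("b", reverse_complement(seq)),
            cfg, bitvec_threshold=0.0,
        )
        assert (rep.lis_score or 0.0) < 0.1

    def test_cdna_mode_recovers_orientation(self, read_factory):
        rng = np.random.default_rng(13)
        seq = random_seq(rng, 200)
        cfg = RunConfig(rna_mode=False)
        rep = compare_reads(
            read_factory("a", seq), read_factory("b", reverse_complement(seq)), cfg
        )
        assert rep.orientation == "-"
        assert rep.lis_score == pytest.approx(1.0)

    def test_bitvec_gate_short_circuits(self, read_factory):
        cfg = RunConfig(rna_mode=True)
        rep = compare_reads(
            read_factory("a", "A" * 100), read_factory("b", "C" * 100),
            cfg, bitvec_threshold=0.4,
        )
        assert rep.lis_score is None
        assert rep.bitvec_score == 0.0


class TestCoveredBases:
    def test_overlapping_intervals_union(self):
        chain = [Triplet(0, 0, 0), Triplet(0, 3, 3), Triplet(0, 30, 30)]
        # [0,10) U [3,13) U [30,40) -> 13 + 10
        assert covered_bases(chain, 10) == 23
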