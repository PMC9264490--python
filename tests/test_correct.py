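"""Block partitioning and the quality-gated consensus correction rules."""

import edlib
import numpy as np

from denovotx.cluster import Cluster
from denovotx.correct import (
    correct_cluster,
    correct_clustering,
    correct_reads,
    partition_blocks,
    weighted_consensus,
)
from denovotx.msa import build_msa
from denovotx.similarity import FORWARD
from denovotx.simulate import SimSpec, generate_dataset
from .test_msa import msa_from_strings


def identity(a: str, b: str) -> float:
    res = edlib.align(a, b)
    return 1 - res["editDistance"] / max(len(a), len(b))


class TestPartitionBlocks:
    def _cluster(self, read_factory, n):
        reads = {f"r{i:03d}": read_factory(f"r{i:03d}", "A" * (1000 - i)) for i in range(n)}
        cluster = Cluster(0, [(rid, FORWARD) for rid in reads], "r000")
        return cluster, reads

    def test_small_cluster_single_block(self, read_factory):
        cluster, reads = self._cluster(read_factory, 100)
        blocks = partition_blocks(cluster, 200, reads)
        assert [len(b) for b in blocks] == [100]

    def test_between_r_and_2r_split_in_half(self, read_factory):
        cluster, reads = self._cluster(read_factory, 300)
        blocks = partition_blocks(cluster, 200, reads)
        assert sorted(len(b) for b in blocks) == [150, 150]

    def test_large_cluster_round_robin(self, read_factory):
        cluster, reads = self._cluster(read_factory, 500)
        blocks = partition_blocks(cluster, 200, reads)
        assert sorted((len(b) for b in blocks), reverse=True) == [167, 167, 166]
        # round-robin by length rank: block j holds ranks j, j+3, j+6, ...
        ranked = sorted(reads, key=lambda rid: (-len(reads[rid]), rid))
        for j, block in enumerate(blocks):
            assert block == ranked[j::3]


class TestCorrectionRules:
    def _column_msa(self, n_consensus, n_other, row_err, mean_consensus_err):
        """Single informative column: n_consensus 'A's, n_other 'G's; the
        last row is the discordant read under test."""
        rows = ["A"] * n_consensus + ["G"] * n_other
        msa = msa_from_strings(rows)
        msa.row_err[: n_consensus, 0] = mean_consensus_err
        msa.row_err[-1, 0] = row_err
        return msa

    def test_high_error_base_corrected(self, cfg):
        # freq 0.7, row err 0.1 > (1/3) * 0.05: substituted
        msa = self._column_msa(7, 3, row_err=0.1, mean_consensus_err=0.05)
        block = correct_reads(msa, cfg)
        assert block.reads[-1].seq == "A"

    def test_trusted_base_kept(self, cfg):
        # row err 0.005 <= (1/3) * 0.05: the read base wins over the consensus
        msa = self._column_msa(7, 3, row_err=0.005, mean_consensus_err=0.05)
        block = correct_reads(msa, cfg)
        assert block.reads[-1].seq == "G"

    def test_below_frequency_threshold_not_corrected(self, cfg):
        # consensus frequency 0.5 < 0.6: no corrections at all
        msa = self._column_msa(5, 5, row_err=0.9, mean_consensus_err=0.05)
        block = correct_reads(msa, cfg)
        assert block.reads[-1].seq == "G"

    def test_exact_threshold_corrects(self, cfg):
        # frequency exactly 0.60 satisfies "at least 60%"
        msa = self._column_msa(6, 4, row_err=0.9, mean_consensus_err=0.05)
        block = correct_reads(msa, cfg)
        assert block.reads[-1].seq == "A"

    def test_insertion_fills_internal_gap_without_guard(self, cfg):
        rows = ["ACT"] * 7 + ["A-T"] * 3
        msa = msa_from_strings(rows, qual=3.0)  # high error probability
        block = correct_reads(msa, cfg)
        assert all(r.seq == "ACT" for r in block.reads)

    def test_deletion_removes_minority_insertion(self, cfg):
        rows = ["A-T"] * 7 + ["ACT"] * 3
        msa = msa_from_strings(rows)
        block = correct_reads(msa, cfg)
        assert all(r.seq == "AT" for r in block.reads)

    def test_sparse_columns_never_correct(self, cfg):
        # only 2 spanning rows: below the evidence floor, leave untouched
        msa = msa_from_strings(["A", "G"])
        block = correct_reads(msa, cfg)
        assert block.reads[1].seq == "G"


class TestCorrectCluster:
    def _simulated_cluster(self, n_reads, seed):
        ds = generate_dataset(
            SimSpec(n_genes=1, reads_per_transcript=n_reads,
                    n_exons=3, exon_len_range=(250, 400), seed=seed)
        )
        reads = {r.read_id: r for r in ds.reads}
        cluster = Cluster(0, [(r.read_id, FORWARD) for r in ds.reads],
                          ds.reads[0].read_id, level="transcript", gene_id=0)
        return cluster, reads, ds.genes[0].isoform_seq(0), ds.reads

    def test_cluster_at_retention_threshold_skipped(self, read_factory, cfg):
        reads = {f"r{i}": read_factory(f"r{i}", "ACGT" * 50) for i in range(5)}
        cluster = Cluster(0, [(rid, FORWARD) for rid in reads], "r0")
        corrected, consensus = correct_cluster(cluster, reads, cfg)
        assert corrected is None and consensus is None

    def test_identical_reads_are_fixed_point(self, read_factory, cfg):
        seq = "ACGTTGCAACGT" * 20
        reads = {f"r{i}": read_factory(f"r{i}", seq) for i in range(6)}
        cluster = Cluster(0, [(rid, FORWARD) for rid in reads], "r0")
        corrected, consensus = correct_cluster(cluster, reads, cfg)
        assert all(r.seq == seq for r in corrected)
        assert consensus.seq == seq
        assert consensus.n_reads == 6

    def test_simulated_cluster_consensus_and_read_identity(self, rna_cfg):
        cluster, reads, truth, sim_reads = self._simulated_cluster(60, seed=13)
        corrected, consensus = correct_cluster(cluster, reads, rna_cfg)
        assert identity(consensus.seq, truth) >= 0.995
        assert abs(len(consensus.seq) - len(truth)) / len(truth) <= 0.02
        raw = np.median([
            identity(r.seq, truth[r.tstart:r.tend]) for r in sim_reads
        ])
        by_id = {r.read_id: r for r in corrected}
        fixed = np.median([
            identity(by_id[r.read_id].seq, truth[r.tstart:r.tend]) for r in sim_reads
        ])
        assert fixed > raw

    def test_multi_block_path(self, rna_cfg):
        cluster, reads, truth, _ = self._simulated_cluster(30, seed=17)
        cfg = rna_cfg.replace(block_size=10)  # forces ceil(30/10) = 3 blocks
        corrected, consensus = correct_cluster(cluster, reads, cfg)
        assert len(corrected) == 30
        assert identity(consensus.seq, truth) >= 0.99


class TestWeightedConsensus:
    def test_support_outvotes_alphabetical_order(self, read_factory):
        # two rows disagreeing at one column: higher read support must win
        r1 = read_factory("a", "ACGTACGTGACGT")
        r2 = read_factory("b", "ACGTACGTTACGT")
        msa = build_msa([r1, r2])
        s1 = np.full(13, 90)
        s2 = np.full(13, 140)
        seq, qual, support = weighted_consensus(msa, [s1, s2], [100, 150])
        assert seq == r2.seq  # 'T' (support 140) beats 'G' (90) despite order
        assert support[8] == 140

    def test_single_row_junk_loses_to_gap_majority(self, read_factory):
        r1 = read_factory("a", "ACGTACGTACGTAAAA")
        r2 = read_factory("b", "ACGTACGTACGT")
        r3 = read_factory("c", "ACGTACGTACGT")
        msa = build_msa([r1, r2, r3])
        seq, _, _ = weighted_consensus(
            msa, [None, None, None], [5, 100, 100]
        )
        assert seq == "ACGTACGTACGT"


class TestCorrectClustering:
    def test_read_conservation_across_outputs(self, rna_cfg):
        ds = generate_dataset(SimSpec(n_genes=3, reads_per_transcript=8, seed=23))
        from denovotx.cluster import cluster_genes
        from denovotx.isoform import split_all

        reads = {r.read_id: r for r in ds.reads}
        tx = split_all(cluster_genes(ds.reads, rna_cfg), reads, rna_cfg)
        result = correct_clustering(tx, reads, rna_cfg)
        out_ids = sorted(
            [r.read_id for r in result.corrected]
            + [r.read_id for r in result.uncorrected]
        )
        assert out_ids == sorted(reads)
        assert sum(c.n_reads for c in result.consensi) == len(result.corrected)
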