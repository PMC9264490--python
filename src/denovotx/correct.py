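"""Quality-gated consensus error correction within transcript clusters.

Each retained cluster (more than ``min_cluster_reads`` members) is divided
into blocks of at most ``block_size`` reads, filled round-robin from the
length-sorted members so that every block spans the cluster's length range.
Each block is aligned, terminal artifacts are trimmed, and every read base
is compared against its column's consensus: a disagreeing base is replaced
when the consensus base reaches the ``consensus_freq`` threshold (60% by
default) — unless the read base's own error probability is at most
``err_ratio_guard`` (1/3) times the mean error probability of the reads
carrying the consensus base, in which case the read is trusted over the
consensus.  Indels are corrected by the same frequency rule without the
error-probability guard.  Block consensus sequences are then re-aligned to
produce the cluster consensus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cluster import Cluster, Clustering, _length_order
from .config import RunConfig
from .io import MAX_PHRED, Read, phred_to_err, reverse_read
from .msa import GAP, Msa, _SYMBOLS, all_column_stats, build_msa, trim_terminal_blocks
from .similarity import FORWARD


def partition_blocks(cluster: Cluster, R: int, reads: dict[str, Read]) -> list[list[str]]:
    """Split a cluster's members into length-balanced correction blocks.

    With N members: one block if N < R, two if R <= N < 2R, otherwise
    K = ceil(N/R).  Members are sorted by descending length and dealt
    round-robin, so block j holds length ranks j, K+j, 2K+j, ...
    """
    if R < 1:
        raise ValueError("block size must be >= 1")
    ranked = _length_order(cluster.read_ids, reads)
    n = len(ranked)
    if n < R:
        k = 1
    elif n < 2 * R:
        k = 2
    else:
        k = -(-n // R)
    return [ranked[j::k] for j in range(k)]


def oriented_read(read: Read, orientation: str) -> Read:
    return read if orientation == FORWARD else reverse_read(read)


@dataclass
class CorrectedBlock:
    reads: list[Read]  # corrected, still on the cluster strand
    consensus_seq: str
    consensus_qual: np.ndarray
    consensus_support: np.ndarray  # reads carrying the consensus base, per position


def correct_reads(msa: Msa, cfg: RunConfig, min_evidence: int = 3) -> CorrectedBlock:
    """Apply the column-consensus correction rules to one aligned block.

    Columns spanned by fewer than ``min_evidence`` rows never correct and
    are excluded from the block consensus (too little evidence; this also
    suppresses spurious terminal columns created by a handful of insertion
    errors beyond the true transcript ends).  Also returns the block's
    column-wise consensus with per-column mean PHRED quality and per-column
    read support.
    """
    consensus, freq, mean_err, n_spanning, counts = all_column_stats(msa)
    spanning = msa.spanning_mask()
    cons_row = consensus[None, :]
    col_ok = (n_spanning >= min_evidence) & (freq >= cfg.consensus_freq)

    is_base = msa.matrix != GAP
    cons_is_base = cons_row != GAP
    disagree = msa.matrix != cons_row

    # (a) base vs base: substitute unless the read base is individually
    # trustworthy (err <= guard * mean consensus err)
    with np.errstate(invalid="ignore"):
        guarded = msa.row_err <= cfg.err_ratio_guard * mean_err[None, :]
    sub = col_ok[None, :] & spanning & disagree & is_base & cons_is_base & ~guarded
    # (b) internal gap vs consensus base: insert (no guard)
    ins = col_ok[None, :] & spanning & ~is_base & cons_is_base
    # (c) base vs consensus gap: delete (no guard)
    dele = col_ok[None, :] & spanning & is_base & ~cons_is_base

    new_matrix = msa.matrix.copy()
    new_qual = msa.row_qual.copy()
    cons_bases = (msa.matrix == cons_row) & spanning
    with np.errstate(invalid="ignore"):
        col_cons_phred = np.where(
            cons_bases.any(axis=0),
            np.nansum(np.where(cons_bases, msa.row_qual, np.nan), axis=0)
            / np.maximum(cons_bases.sum(axis=0), 1),
            0.0,
        )
    new_matrix[sub] = np.broadcast_to(cons_row, msa.matrix.shape)[sub]
    new_matrix[ins] = np.broadcast_to(cons_row, msa.matrix.shape)[ins]
    new_qual[ins] = np.broadcast_to(col_cons_phred[None, :], msa.matrix.shape)[ins]
    new_matrix[dele] = GAP
    new_qual[dele] = np.nan

    corrected: list[Read] = []
    for i, rid in enumerate(msa.read_ids):
        keep = new_matrix[i] != GAP
        seq = "".join(_SYMBOLS[c] for c in new_matrix[i][keep])
        qual = np.clip(np.rint(new_qual[i][keep]), 0, MAX_PHRED).astype(int)
        corrected.append(Read(rid, seq, qual))

    keep_cols = (consensus != GAP) & (n_spanning >= min_evidence)
    cons_seq = "".join(_SYMBOLS[c] for c in consensus[keep_cols])
    cons_qual = _column_mean_phred(msa)[keep_cols]
    cons_support = counts[consensus, np.arange(msa.n_cols)][keep_cols]
    return CorrectedBlock(reads=corrected, consensus_seq=cons_seq,
                          consensus_qual=cons_qual,
                          consensus_support=cons_support.astype(int))


def _column_mean_phred(msa: Msa) -> np.ndarray:
    """Mean PHRED of the (non-gap) bases in each column, rounded/clamped."""
    is_base = msa.matrix != GAP
    total = np.where(is_base, np.nan_to_num(msa.row_qual), 0.0).sum(axis=0)
    count = is_base.sum(axis=0)
    mean = total / np.maximum(count, 1)
    return np.clip(np.rint(mean), 0, MAX_PHRED).astype(int)


@dataclass
class ClusterConsensus:
    """Draft transcript: consensus of one corrected transcript cluster.

    ``support`` holds the number of reads carrying the consensus base at
    each position; it weights the vote when consensi are re-aligned during
    polishing (None when unknown, e.g. after a round-trip through FASTQ).
    """

    cluster_id: int
    gene_id: Optional[int]
    seq: str
    qual: np.ndarray
    n_reads: int
    support: Optional[np.ndarray] = None

    # mimic the Read surface so consensi can feed clustering/alignment
    @property
    def read_id(self) -> str:
        return f"cluster_{self.cluster_id}"

    @property
    def err(self) -> np.ndarray:
        return phred_to_err(self.qual)

    def __len__(self) -> int:
        return len(self.seq)


def consensus_of_msa(msa: Msa, min_coverage: int = 1) -> tuple[str, np.ndarray]:
    """Column-wise consensus and mean-PHRED quality of an alignment.

    Columns whose consensus is a gap, or spanned by fewer than
    ``min_coverage`` rows, are omitted from the consensus sequence.
    """
    consensus, _, _, n_spanning, _ = all_column_stats(msa)
    keep = (consensus != GAP) & (n_spanning >= min_coverage)
    seq = "".join(_SYMBOLS[c] for c in consensus[keep])
    return seq, _column_mean_phred(msa)[keep]


def weighted_consensus(
    msa: Msa,
    row_supports: list[Optional[np.ndarray]],
    row_weights: list[int],
) -> tuple[str, np.ndarray, np.ndarray]:
    """Read-support-weighted column consensus of re-aligned cluster consensi.

    Each row of ``msa`` is itself a consensus backed by a block (or cluster)
    of reads: a base votes with the number of reads that carried it
    (``row_supports``, falling back to the row's total read count), while a
    row without a base at a column votes gap with its full read count.  A
    column contributes a base to the consensus only when the winning base
    outweighs the gap vote, so spurious terminal columns present in a single
    low-support row are dropped.  Returns (sequence, PHRED quality, support).
    """
    n_rows, n_cols = msa.matrix.shape
    support = np.zeros((n_rows, n_cols))
    for i in range(n_rows):
        nongap = np.flatnonzero(msa.matrix[i] != GAP)
        if row_supports[i] is not None:
            support[i, nongap] = np.asarray(row_supports[i], dtype=float)
        else:
            support[i, nongap] = float(row_weights[i])
    base_votes = np.zeros((4, n_cols))
    for code in range(4):
        base_votes[code] = np.where(msa.matrix == code, support, 0.0).sum(axis=0)
    gap_votes = np.where(
        msa.matrix == GAP, np.asarray(row_weights, dtype=float)[:, None], 0.0
    ).sum(axis=0)
    best = base_votes.argmax(axis=0).astype(np.int8)
    best_votes = base_votes[best, np.arange(n_cols)]
    keep = best_votes > gap_votes
    seq = "".join(_SYMBOLS[c] for c in best[keep])
    qual = _column_mean_phred(msa)[keep]
    out_support = np.rint(best_votes[keep]).astype(int)
    return seq, qual, out_support


def correct_cluster(
    cluster: Cluster, reads: dict[str, Read], cfg: RunConfig
) -> tuple[Optional[list[Read]], Optional[ClusterConsensus]]:
    """Correct one transcript cluster; skipped if it is too small.

    Returns (corrected reads on their ORIGINAL strand, cluster consensus),
    or (None, None) for clusters with <= ``min_cluster_reads`` members.
    """
    if cluster.size <= cfg.min_cluster_reads:
        return None, None
    orient_of = dict(cluster.members)
    oriented = {
        rid: oriented_read(reads[rid], orient_of[rid]) for rid in cluster.read_ids
    }
    blocks = partition_blocks(cluster, cfg.block_size, reads)
    block_results: list[CorrectedBlock] = []
    for block_ids in blocks:
        msa = build_msa([oriented[rid] for rid in block_ids], engine=cfg.msa_engine)
        trim_terminal_blocks(msa)
        block_results.append(correct_reads(msa, cfg))

    if len(block_results) == 1:
        cons_seq = block_results[0].consensus_seq
        cons_qual = block_results[0].consensus_qual
        cons_support = block_results[0].consensus_support
    else:
        pseudo = [
            Read(f"block_{b}", res.consensus_seq, res.consensus_qual)
            for b, res in enumerate(block_results)
        ]
        final_msa = build_msa(pseudo, engine=cfg.msa_engine)
        cons_seq, cons_qual, cons_support = weighted_consensus(
            final_msa,
            [res.consensus_support for res in block_results],
            [len(b) for b in blocks],
        )

    corrected: list[Read] = []
    for res in block_results:
        for r in res.reads:
            if orient_of[r.read_id] == FORWARD:
                corrected.append(r)
            else:
                corrected.append(reverse_read(r))
    order = {rid: i for i, rid in enumerate(cluster.read_ids)}
    corrected.sort(key=lambda r: order[r.read_id])
    consensus = ClusterConsensus(
        cluster_id=cluster.cluster_id,
        gene_id=cluster.gene_id,
        seq=cons_seq,
        qual=cons_qual,
        n_reads=cluster.size,
        support=cons_support,
    )
    return corrected, consensus


@dataclass
class CorrectionResult:
    corrected: list[Read]
    uncorrected: list[Read]
    consensi: list[ClusterConsensus]
    retained: list[Cluster]  # clusters that were corrected


def correct_clustering(
    clustering: Clustering, reads: dict[str, Read], cfg: RunConfig
) -> CorrectionResult:
    """Correct every retained transcript cluster in a clustering."""
    corrected: list[Read] = []
    uncorrected: list[Read] = []
    consensi: list[ClusterConsensus] = []
    retained: list[Cluster] = []
    for cluster in clustering.clusters:
        reads_out, consensus = correct_cluster(cluster, reads, cfg)
        if consensus is None:
            uncorrected.extend(reads[rid] for rid in cluster.read_ids)
            continue
        corrected.extend(reads_out)
        consensi.append(consensus)
        retained.append(cluster)
    return CorrectionResult(corrected, uncorrected, consensi, retained)
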