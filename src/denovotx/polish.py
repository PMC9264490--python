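"""Polishing of transcript clusters and quantification.

Error correction can leave reads from one transcript split across several
clusters (under-clustering).  Polishing re-runs the greedy two-step
clustering over the cluster consensus sequences; clusters that co-cluster
are merged, their consensi are re-aligned into the final transcript
consensus, and the abundance of the transcript is the total read count of
the merged cluster.  Gene assignments follow the merge: a merge within one
gene stays in that gene, a merge across genes moves all transcripts of the
gene with fewer transcripts into the gene with more (ties to the smaller
gene id).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cluster import cluster_genes
from .config import RunConfig
from .correct import ClusterConsensus, CorrectionResult, weighted_consensus
from .io import Read
from .msa import build_msa
from .similarity import FORWARD, reverse_complement


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    consensus: str
    qual: np.ndarray
    abundance: int

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=int)
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")
        if len(self.consensus) != len(self.qual):
            raise ValueError("consensus/quality length mismatch")


def polish_clusters(
    consensi: Sequence[ClusterConsensus], cfg: RunConfig
) -> list[list[tuple[ClusterConsensus, str]]]:
    """Group transcript clusters whose consensi still co-cluster.

    Returns merge groups as lists of (cluster consensus, orientation vs the
    group strand); singleton groups mean no merge.  Groups are ordered by
    the smallest member cluster id.
    """
    if not consensi:
        return []
    by_rid = {c.read_id: c for c in consensi}
    meta = cluster_genes(list(consensi), cfg)
    groups: list[list[tuple[ClusterConsensus, str]]] = []
    for mc in meta.clusters:
        group = [(by_rid[rid], orient) for rid, orient in mc.members]
        group.sort(key=lambda e: e[0].cluster_id)
        groups.append(group)
    groups.sort(key=lambda g: g[0][0].cluster_id)
    return groups


def reassign_genes(
    groups: Sequence[Sequence[tuple[ClusterConsensus, str]]],
    gene_map: dict[int, int],
) -> dict[int, int]:
    """Resolve gene ids after merging; the larger gene absorbs the smaller.

    ``gene_map`` maps transcript cluster id -> provisional gene id.  For a
    merge across genes, ALL transcripts of the gene with fewer transcripts
    move into the gene with more (ties to the smaller gene id).  Merges are
    processed in group order, so cascading absorptions are deterministic.
    """
    gene_map = dict(gene_map)
    for group in groups:
        genes = sorted({gene_map[c.cluster_id] for c, _ in group})
        if len(genes) < 2:
            continue
        sizes = {
            g: sum(1 for v in gene_map.values() if v == g) for g in genes
        }
        winner = min(genes, key=lambda g: (-sizes[g], g))
        for g in genes:
            if g == winner:
                continue
            for cid, gid in gene_map.items():
                if gid == g:
                    gene_map[cid] = winner
    return gene_map


def finalize_transcripts(
    groups: Sequence[Sequence[tuple[ClusterConsensus, str]]],
    gene_map: dict[int, int],
    cfg: RunConfig,
) -> list[Transcript]:
    """Build the final quantified transcripts from merge groups.

    A singleton group keeps its cluster consensus; a merged group re-aligns
    the member consensi (on the group strand) and takes the column consensus
    with per-column mean PHRED quality.  Abundance is the total read count
    of the group.  Transcript ids are assigned in descending abundance.
    """
    drafts: list[tuple[int, int, str, np.ndarray, int]] = []
    for group in groups:
        abundance = sum(c.n_reads for c, _ in group)
        lead = group[0][0]
        if len(group) == 1:
            seq, qual = lead.seq, lead.qual
        else:
            pseudo, supports, weights = [], [], []
            for c, orient in group:
                if orient == FORWARD:
                    pseudo.append(Read(c.read_id, c.seq, c.qual))
                    supports.append(c.support)
                else:
                    pseudo.append(
                        Read(c.read_id, reverse_complement(c.seq), c.qual[::-1].copy())
                    )
                    supports.append(
                        None if c.support is None else c.support[::-1].copy()
                    )
                weights.append(c.n_reads)
            msa = build_msa(pseudo, engine=cfg.msa_engine)
            seq, qual, _ = weighted_consensus(msa, supports, weights)
        drafts.append(
            (lead.cluster_id, gene_map[lead.cluster_id], seq, qual, abundance)
        )
    drafts.sort(key=lambda d: (-d[4], d[0]))
    return [
        Transcript(
            transcript_id=f"tx_{i}",
            gene_id=f"gene_{gid}",
            consensus=seq,
            qual=qual,
            abundance=abundance,
        )
        for i, (_, gid, seq, qual, abundance) in enumerate(drafts)
    ]


def polish_and_quantify(
    correction: CorrectionResult, cfg: RunConfig
) -> list[Transcript]:
    """Full polishing stage: merge, reassign genes, emit final transcripts."""
    consensi = correction.consensi
    groups = polish_clusters(consensi, cfg)
    gene_map = {
        c.cluster_id: (c.gene_id if c.gene_id is not None else c.cluster_id)
        for c in consensi
    }
    gene_map = reassign_genes(groups, gene_map)
    return finalize_transcripts(groups, gene_map, cfg)
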