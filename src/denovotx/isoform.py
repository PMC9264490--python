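"""Splitting gene clusters into transcript (isoform) clusters.

Two reads from the same gene but different isoforms — e.g. with and without
an internal exon — still share their flanking sequence, so their co-linear
k-mer chain survives, but the chain's inter-k-mer spacing jumps by the exon
length exactly once.  The gap-difference variance of the chain captures
this: reads are placed in different transcript clusters when the variance
exceeds ``iso_max_variance``.  Grouping reuses the greedy representative
scheme of the gene stage, with the isoform-stage k-mer size (default 11)
and LIS threshold (default 0.30); the bit-vector gate is disabled because
cluster membership already implies gene-level similarity.
"""

from __future__ import annotations

from typing import Optional

from .cluster import Cluster, Clustering, _length_order, select_representative
from .config import RunConfig
from .io import Read
from .similarity import SimilarityReport, SketchStore, lis_similarity


def variance_decision(report: SimilarityReport, cfg: RunConfig) -> str:
    """'different_isoform' iff the chain's gap variance exceeds the threshold."""
    if report.gap_variance > cfg.iso_max_variance:
        return "different_isoform"
    return "same_isoform"


def split_gene_cluster(
    cluster: Cluster,
    reads: dict[str, Read],
    cfg: RunConfig,
    store: Optional[SketchStore] = None,
    next_id: int = 0,
) -> list[Cluster]:
    """Greedy sub-clustering of one gene cluster into transcript clusters.

    Members are visited in descending-length order; a read joins the first
    sub-cluster whose representative it matches with ``lis_score >=
    iso_score_threshold`` and gap variance within ``iso_max_variance``,
    otherwise it founds a new sub-cluster.  Reads whose chains against every
    representative are too short for a variance estimate (< 3 members) fall
    back to the best-scoring sub-cluster above the score threshold.  The
    sub-clusters partition the gene cluster.
    """
    if store is None:
        store = SketchStore()
    orient_of = dict(cluster.members)

    subclusters: list[Cluster] = []
    for rid in _length_order(cluster.read_ids, reads):
        read = reads[rid]
        placed = False
        best_fallback: tuple[float, int] | None = None  # (score, subcluster idx)
        all_short = True
        for idx, sub in enumerate(subclusters):
            rep = reads[sub.representative_id]
            # both sequences are put on the gene cluster's strand, so a
            # single forward LIS comparison suffices
            report = lis_similarity(
                store.oriented_seq(rep, orient_of[sub.representative_id]),
                store.oriented_seq(read, orient_of[rid]),
                cfg.iso_kmer_size,
            )
            score = report.lis_score or 0.0
            if len(report.chain) >= 3:
                all_short = False
            if (
                score >= cfg.iso_score_threshold
                and variance_decision(report, cfg) == "same_isoform"
            ):
                sub.members.append((rid, orient_of[rid]))
                placed = True
                break
            if score >= cfg.iso_score_threshold and (
                best_fallback is None or score > best_fallback[0]
            ):
                best_fallback = (score, idx)
        if not placed and all_short and best_fallback is not None:
            subclusters[best_fallback[1]].members.append((rid, orient_of[rid]))
            placed = True
        if not placed:
            subclusters.append(
                Cluster(next_id + len(subclusters), [(rid, orient_of[rid])],
                        rid, level="transcript", gene_id=cluster.cluster_id)
            )
    for sub in subclusters:
        sub.representative_id = select_representative(sub, reads, cfg.p_repr)
    return subclusters


def split_all(
    clustering: Clustering,
    reads: dict[str, Read],
    cfg: RunConfig,
    store: Optional[SketchStore] = None,
) -> Clustering:
    """Split every gene cluster; transcript cluster ids are globally unique."""
    if store is None:
        store = SketchStore()
    out: list[Cluster] = []
    next_id = 0
    for cluster in clustering.clusters:
        subs = split_gene_cluster(cluster, reads, cfg, store=store, next_id=next_id)
        next_id += len(subs)
        out.extend(subs)
    return Clustering(out)
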