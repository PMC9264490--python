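"""Greedy iterative clustering of reads into gene-level clusters.

Reads are sorted by descending length and processed one at a time: a read
joins the first existing cluster whose representative it matches above both
the current bit-vector threshold and the (fixed) LIS threshold, otherwise it
founds a new cluster.  The bit-vector threshold is lowered across iterations
(0.4 -> 0.2 in steps of 0.05 by default), each of which also merges clusters
whose representatives are mutually similar; a final pass at bit-vector
threshold 0.0 compares all remaining singletons and cluster representatives
with the LIS score alone.  All clusters keep every member's orientation
relative to the cluster strand, so downstream alignment sees a single strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .config import RunConfig
from .io import Read
from .similarity import FORWARD, REVERSE, SketchStore, compare_reads


@dataclass
class Cluster:
    cluster_id: int
    members: list[tuple[str, str]]  # (read_id, orientation vs cluster strand)
    representative_id: str
    level: str = "gene"
    gene_id: Optional[int] = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def read_ids(self) -> list[str]:
        return [rid for rid, _ in self.members]

    def orientation_of(self, read_id: str) -> str:
        for rid, orient in self.members:
            if rid == read_id:
                return orient
        raise KeyError(read_id)


@dataclass
class Clustering:
    clusters: list[Cluster]

    @property
    def assignment(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clusters:
            for rid, _ in c.members:
                if rid in out:
                    raise ValueError(f"read {rid!r} assigned to multiple clusters")
                out[rid] = c.cluster_id
        return out

    @property
    def n_reads(self) -> int:
        return sum(c.size for c in self.clusters)


def threshold_schedule(cfg: RunConfig) -> tuple[float, ...]:
    """Descending bit-vector thresholds from B_init to b_final, then 0.0."""
    if cfg.b_final > cfg.B_init:
        raise ValueError("b_final must not exceed B_init")
    out: list[float] = []
    t = cfg.B_init
    while t > cfg.b_final - 1e-9:
        out.append(round(t, 10))
        t -= cfg.f_step
    out.append(0.0)
    return tuple(out)


def _length_order(read_ids: Iterable[str], reads: dict[str, Read]) -> list[str]:
    return sorted(read_ids, key=lambda rid: (-len(reads[rid]), rid))


def select_representative(cluster: Cluster, reads: dict[str, Read], p_repr: float) -> str:
    """Read at fractional rank ``p_repr`` of the descending-length ordering.

    With N members the representative is the member at 0-based index
    floor(p_repr * N); length ties break by read id.
    """
    ranked = _length_order(cluster.read_ids, reads)
    return ranked[int(p_repr * len(ranked))]


def _compose(o1: str, o2: str) -> str:
    return FORWARD if o1 == o2 else REVERSE


def _passes(report, threshold: float, cfg: RunConfig) -> bool:
    return (
        report.lis_computed
        and report.bitvec_score >= threshold
        and report.lis_score >= cfg.s_lis
    )


def greedy_pass(
    state: Clustering,
    unclustered: list[Read],
    threshold: float,
    cfg: RunConfig,
    reads: dict[str, Read],
    store: Optional[SketchStore] = None,
    next_id: Optional[int] = None,
) -> int:
    """One clustering iteration at a fixed bit-vector threshold.

    Unclustered reads are assigned greedily (first passing cluster in
    creation order wins, else a new cluster is founded); afterwards cluster
    representatives are compared pairwise and mutually similar clusters are
    merged (transitively within the pass, the smaller cluster id surviving).
    Representatives are recomputed at the end of the pass.  Returns the next
    unused cluster id.
    """
    if store is None:
        store = SketchStore()
    if next_id is None:
        next_id = max((c.cluster_id for c in state.clusters), default=-1) + 1

    for read in unclustered:
        placed = False
        for cluster in state.clusters:
            rep = reads[cluster.representative_id]
            rep_orient = cluster.orientation_of(cluster.representative_id)
            report = compare_reads(
                rep, read, cfg, stage="gene", bitvec_threshold=threshold,
                store=store, orientation1=rep_orient,
            )
            if _passes(report, threshold, cfg):
                cluster.members.append((read.read_id, report.orientation))
                placed = True
                break
        if not placed:
            state.clusters.append(
                Cluster(next_id, [(read.read_id, FORWARD)], read.read_id)
            )
            next_id += 1

    # pairwise representative comparison; union-find (with strand parity)
    # makes merging transitive within the pass
    n = len(state.clusters)
    parent = list(range(n))
    rel = [FORWARD] * n  # orientation of node's strand vs its parent's strand

    def find(x: int) -> tuple[int, str]:
        orient = FORWARD
        while parent[x] != x:
            orient = _compose(orient, rel[x])
            x = parent[x]
        return x, orient

    for i in range(n):
        for j in range(i + 1, n):
            ri, oi = find(i)
            rj, oj = find(j)
            if ri == rj:
                continue
            ci, cj = state.clusters[i], state.clusters[j]
            rep_i = reads[ci.representative_id]
            rep_j = reads[cj.representative_id]
            report = compare_reads(
                rep_i, rep_j, cfg, stage="gene", bitvec_threshold=threshold,
                store=store, orientation1=ci.orientation_of(ci.representative_id),
            )
            if _passes(report, threshold, cfg):
                # report.orientation is rep_j's read strand vs i's cluster
                # strand; compose with rep_j's strand within j to get j's
                # cluster strand vs i's, then lift both ends to their roots
                flip_ij = _compose(
                    report.orientation, cj.orientation_of(cj.representative_id)
                )
                parent[rj] = ri
                rel[rj] = _compose(oj, _compose(flip_ij, oi))

    groups: dict[int, list[tuple[int, str]]] = {}
    for i in range(n):
        root, orient = find(i)
        groups.setdefault(root, []).append((i, orient))

    # clusters are kept in ascending-id order, so i < j implies smaller id;
    # every root is therefore the smallest-id cluster of its group and the
    # merged cluster inherits its id and strand
    merged: list[Cluster] = []
    for root in sorted(groups, key=lambda r: state.clusters[r].cluster_id):
        entries = groups[root]
        if len(entries) == 1:
            merged.append(state.clusters[root])
            continue
        keep_id = state.clusters[root].cluster_id
        members: list[tuple[str, str]] = []
        for i, flip in sorted(entries, key=lambda e: state.clusters[e[0]].cluster_id):
            for rid, orient in state.clusters[i].members:
                members.append((rid, _compose(orient, flip)))
        merged.append(Cluster(keep_id, members, members[0][0]))
    state.clusters = merged

    for cluster in state.clusters:
        cluster.representative_id = select_representative(cluster, reads, cfg.p_repr)
    return next_id


def cluster_genes(
    reads: list[Read], cfg: RunConfig, store: Optional[SketchStore] = None
) -> Clustering:
    """Run the full threshold schedule and return the gene-level partition."""
    if store is None:
        store = SketchStore()
    reads_by_id = {r.read_id: r for r in reads}
    if len(reads_by_id) != len(reads):
        raise ValueError("duplicate read ids in input")
    ordered = sorted(reads, key=lambda r: (-len(r), r.read_id))
    state = Clustering(clusters=[])
    next_id = 0
    pending = ordered
    for threshold in threshold_schedule(cfg):
        next_id = greedy_pass(state, pending, threshold, cfg, reads_by_id,
                              store=store, next_id=next_id)
        pending = []
    # compact ids in creation order
    for new_id, cluster in enumerate(sorted(state.clusters, key=lambda c: c.cluster_id)):
        cluster.cluster_id = new_id
    state.clusters.sort(key=lambda c: c.cluster_id)
    return state
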