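"""Two-step read-pair similarity.

Step one is a fast, approximate comparison: every k-mer of a read (k = 6 by
default) is hashed by ``H(b1..bk) = 4^(k-1) H(b1) + ... + H(bk)`` with
``H(A)=0, H(C)=1, H(G)=2, H(T)=3`` into a presence bit-vector of length 4^k;
the score of a pair is ``|AND|`` over the larger of the two k-mer counts.

Step two, run only when step one passes a threshold, finds the longest chain
of co-linear shared k-mers (a Longest Increasing Subsequence over matched
k-mer positions) and scores the pair by the fraction of the shorter read
covered by the chain's k-mer intervals.  The variance of the differences
between adjacent inter-k-mer distances along the chain ("gap-difference
variance") is the statistic used downstream to separate isoforms: a skipped
exon shows up as one large jump in an otherwise flat gap profile.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .config import RunConfig
from .io import Read, reverse_complement

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
# ambiguous bases hash as 'A'; rare after length filtering and callers keep
# the original characters in all output sequences
_BASE_CODE_LENIENT = _BASE_CODE.copy()
_BASE_CODE_LENIENT[_BASE_CODE_LENIENT < 0] = 0

FORWARD = "+"
REVERSE = "-"


def hash_kmer(kmer: str) -> int:
    """Integer hash of a k-mer: base-4 value with A,C,G,T -> 0,1,2,3."""
    codes = _BASE_CODE[np.frombuffer(kmer.encode(), dtype=np.uint8)]
    if (codes < 0).any():
        bad = kmer[int(np.argmax(codes < 0))]
        raise ValueError(f"non-ACGT symbol {bad!r} in k-mer {kmer!r}")
    h = 0
    for c in codes:
        h = h * 4 + int(c)
    return h


def kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Rolling hashes of all k-mers of ``seq`` (ambiguous bases as 'A')."""
    if len(seq) < k:
        raise ValueError(f"sequence length {len(seq)} < k={k}")
    codes = _BASE_CODE_LENIENT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows @ powers


@dataclass
class KmerVector:
    """Presence bit-vector over all 4^k possible k-mers of one read."""

    k: int
    bits: np.ndarray  # packed uint64 words
    n_kmers: int

    @property
    def popcount(self) -> int:
        return int(np.bitwise_count(self.bits).sum())


def build_kmer_vector(seq: str | Read, k: int) -> KmerVector:
    if isinstance(seq, Read):
        seq = seq.seq
    hashes = kmer_hashes(seq, k)
    n_words = (4**k + 63) // 64
    bits = np.zeros(n_words, dtype=np.uint64)
    words, offsets = np.divmod(hashes, 64)
    np.bitwise_or.at(bits, words, np.uint64(1) << offsets.astype(np.uint64))
    return KmerVector(k=k, bits=bits, n_kmers=int(np.bitwise_count(bits).sum()))


def bitvec_score(v1: KmerVector, v2: KmerVector) -> float:
    """Shared k-mers over the larger k-mer count of the pair; in [0, 1]."""
    if v1.k != v2.k:
        raise ValueError(f"k mismatch: {v1.k} != {v2.k}")
    common = int(np.bitwise_count(v1.bits & v2.bits).sum())
    denom = max(v1.n_kmers, v2.n_kmers)
    return common / denom if denom else 0.0


class Triplet(NamedTuple):
    """A shared k-mer: hash value plus its position in each read."""

    s: int
    p1: int
    p2: int


def build_triplets(seq1: str, seq2: str, k: int) -> list[Triplet]:
    """All (hash, p1, p2) matches of k-mers shared by the two reads.

    A k-mer occurring at several positions contributes one triplet per
    position pair.  The list is sorted by (p1, p2).
    """
    h2: dict[int, list[int]] = {}
    for p2, h in enumerate(kmer_hashes(seq2, k)):
        h2.setdefault(int(h), []).append(p2)
    triplets: list[Triplet] = []
    for p1, h in enumerate(kmer_hashes(seq1, k)):
        positions = h2.get(int(h))
        if positions:
            for p2 in positions:
                triplets.append(Triplet(int(h), p1, p2))
    triplets.sort(key=lambda t: (t.p1, t.p2))
    return triplets


def _chain_lengths_ending(order: list[int], p2: list[int]) -> list[int]:
    """Patience pass: longest strictly-increasing chain length ending at each
    element, processed in ``order`` (equal-p1 groups in descending p2 so that
    two matches at the same p1 can never chain)."""
    lengths = [0] * len(order)
    tails: list[int] = []
    for i in order:
        idx = bisect_left(tails, p2[i])
        lengths[i] = idx + 1
        if idx == len(tails):
            tails.append(p2[i])
        else:
            tails[idx] = min(tails[idx], p2[i])
    return lengths


def lis_chain(triplets: list[Triplet]) -> list[Triplet]:
    """Maximum-length chain strictly increasing in both p1 and p2.

    Among equally long chains, returns the lexicographically smallest in
    (p1, p2) sequence, which makes the result platform-independent.
    """
    n = len(triplets)
    if n == 0:
        return []
    p1 = [t.p1 for t in triplets]
    p2 = [t.p2 for t in triplets]
    # ending lengths: sort by (p1 asc, p2 desc)
    fwd_order = sorted(range(n), key=lambda i: (p1[i], -p2[i]))
    f = _chain_lengths_ending(fwd_order, p2)
    # starting lengths: mirror both coordinates and repeat
    rev_order = sorted(range(n), key=lambda i: (-p1[i], p2[i]))
    g = _chain_lengths_ending(rev_order, [-x for x in p2])
    total = max(f[i] + g[i] - 1 for i in range(n))
    # greedy reconstruction over the (p1, p2)-sorted list: picking the first
    # feasible element at each rank yields the lexicographically smallest
    # maximum chain
    chain: list[Triplet] = []
    prev_p1 = prev_p2 = -1
    i = 0
    for rank in range(total):
        need = total - rank
        while True:
            t = triplets[i]
            if g[i] >= need and t.p1 > prev_p1 and t.p2 > prev_p2:
                chain.append(t)
                prev_p1, prev_p2 = t.p1, t.p2
                i += 1
                break
            i += 1
    return chain


def covered_bases(chain: list[Triplet], k: int) -> int:
    """Total length of the union of [p1, p1+k) intervals along the chain."""
    covered = 0
    end = -1
    for t in chain:
        start = max(t.p1, end)
        covered += max(0, t.p1 + k - start)
        end = max(end, t.p1 + k)
    return covered


def gap_variance(chain: list[Triplet]) -> float:
    """Population variance of adjacent gap-length differences along a chain.

    For consecutive chain members the gap difference is
    ``d = (p1' - p1) - (p2' - p2)``; an exon present in read 1 but absent in
    read 2 yields one ``d`` near the exon length.  Chains with fewer than two
    gaps have variance 0.
    """
    if len(chain) < 3:
        return 0.0
    d = np.array(
        [
            (chain[i + 1].p1 - chain[i].p1) - (chain[i + 1].p2 - chain[i].p2)
            for i in range(len(chain) - 1)
        ],
        dtype=float,
    )
    return float(np.var(d))


@dataclass
class SimilarityReport:
    """Outcome of comparing a pair of reads."""

    bitvec_score: float
    lis_score: Optional[float] = None  # None: gate not passed, LIS skipped
    chain: list[Triplet] = field(default_factory=list)
    gap_variance: float = 0.0
    orientation: str = FORWARD

    @property
    def lis_computed(self) -> bool:
        return self.lis_score is not None


def lis_similarity(seq1: str | Read, seq2: str | Read, k: int) -> SimilarityReport:
    """LIS-chain similarity of two sequences in their given orientation."""
    if isinstance(seq1, Read):
        seq1 = seq1.seq
    if isinstance(seq2, Read):
        seq2 = seq2.seq
    if len(seq1) < k or len(seq2) < k:
        return SimilarityReport(bitvec_score=0.0, lis_score=0.0)
    chain = lis_chain(build_triplets(seq1, seq2, k))
    score = covered_bases(chain, k) / min(len(seq1), len(seq2))
    return SimilarityReport(
        bitvec_score=0.0,
        lis_score=score,
        chain=chain,
        gap_variance=gap_variance(chain),
    )


class SketchStore:
    """Per-read cache of k-mer vectors and sequences in both orientations."""

    def __init__(self) -> None:
        self._vectors: dict[tuple[str, str, int], KmerVector] = {}
        self._rc: dict[str, str] = {}

    def rc_seq(self, read: Read) -> str:
        seq = self._rc.get(read.read_id)
        if seq is None:
            seq = reverse_complement(read.seq)
            self._rc[read.read_id] = seq
        return seq

    def oriented_seq(self, read: Read, orientation: str) -> str:
        return read.seq if orientation == FORWARD else self.rc_seq(read)

    def vector(self, read: Read, orientation: str, k: int) -> KmerVector:
        key = (read.read_id, orientation, k)
        v = self._vectors.get(key)
        if v is None:
            v = build_kmer_vector(self.oriented_seq(read, orientation), k)
            self._vectors[key] = v
        return v


def compare_reads(
    read1: Read,
    read2: Read,
    cfg: RunConfig,
    stage: str = "gene",
    bitvec_threshold: Optional[float] = None,
    store: Optional[SketchStore] = None,
    orientation1: str = FORWARD,
) -> SimilarityReport:
    """Full two-step comparison of a read pair.

    ``read1`` (taken in ``orientation1``) is the reference strand, e.g. a
    cluster representative oriented onto its cluster's strand; in cDNA mode
    both orientations of ``read2`` are tried and the one with the higher LIS
    score wins.  The bit-vector gate applies per orientation; if no
    orientation passes it the report carries the best bit-vector score with
    ``lis_score=None``.
    """
    if store is None:
        store = SketchStore()
    if bitvec_threshold is None:
        bitvec_threshold = cfg.b_final
    k = cfg.k_lis if stage == "gene" else cfg.iso_kmer_size
    orientations = (FORWARD,) if cfg.rna_mode else (FORWARD, REVERSE)

    seq1 = store.oriented_seq(read1, orientation1)
    v1 = store.vector(read1, orientation1, cfg.k_bitvec)
    best: Optional[SimilarityReport] = None
    best_bitvec = 0.0
    for orient in orientations:
        bv = bitvec_score(v1, store.vector(read2, orient, cfg.k_bitvec))
        best_bitvec = max(best_bitvec, bv)
        if bv < bitvec_threshold:
            continue
        rep = lis_similarity(seq1, store.oriented_seq(read2, orient), k)
        rep.bitvec_score = bv
        rep.orientation = orient
        if best is None or rep.lis_score > best.lis_score:
            best = rep
    if best is None:
        return SimilarityReport(bitvec_score=best_bitvec, lis_score=None)
    return best
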