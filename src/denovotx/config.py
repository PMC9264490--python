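"""Run configuration for the clustering / correction / polishing pipeline.

All tunables of the pipeline live in a single :class:`RunConfig` so that every
stage sees one consistent, hashable parameter set.  Defaults follow the
published tool defaults (bit-vector threshold schedule 0.4 -> 0.2 in steps of
0.05, LIS score threshold 0.2, representative rank fraction 0.15, isoform
stage k=11 / score 0.30 / max gap variance 25, correction block size 200,
60% consensus rule with the 1/3 error-probability guard, >5-read cluster
retention, and the 150-nt input length filter).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class RunConfig:
    """Parameters controlling every stage of the pipeline.

    Attributes
    ----------
    k_bitvec:
        k-mer size for the fast bit-vector similarity (fixed at 6 by
        default; capped at 15 so hashes fit comfortably in signed 32-bit).
    k_lis:
        k-mer size for the sensitive LIS-based similarity at the gene stage.
    B_init, b_final, f_step:
        Initial / final bit-vector thresholds and the decrement between
        clustering iterations.  A terminal 0.0 pass always follows.
    s_lis:
        LIS score threshold, fixed over the entire clustering process.
    p_repr:
        Fractional rank (into the descending-length ordering of a cluster's
        members) of the representative read.
    iso_max_variance:
        Gap-difference variance above which two reads are deemed to come
        from different isoforms.
    iso_score_threshold, iso_kmer_size:
        LIS threshold and k-mer size used at the isoform-splitting stage.
    block_size:
        Reads per correction block (R).
    consensus_freq:
        Minimum column-consensus frequency for a correction to apply.
    err_ratio_guard:
        A mismatching base is NOT corrected when its own error probability
        is <= err_ratio_guard * (mean error probability of the reads
        carrying the consensus base in that column).
    min_cluster_reads:
        Clusters must have strictly more members than this to be corrected
        and retained as transcripts.
    min_read_len:
        Reads of this length or shorter are filtered out up front.
    rna_mode:
        If True, reads are single-stranded (dRNA); only the forward
        orientation is tested.  If False (cDNA), both orientations are.
    seed:
        Seed for the simulator; the pipeline proper is deterministic.
    """

    k_bitvec: int = 6
    k_lis: int = 10
    B_init: float = 0.4
    b_final: float = 0.2
    f_step: float = 0.05
    s_lis: float = 0.2
    p_repr: float = 0.15
    iso_max_variance: float = 25.0
    iso_score_threshold: float = 0.30
    iso_kmer_size: int = 11
    block_size: int = 200
    consensus_freq: float = 0.60
    err_ratio_guard: float = 1.0 / 3.0
    min_cluster_reads: int = 5
    min_read_len: int = 150
    rna_mode: bool = False
    seed: int = 0
    msa_engine: str = "mafft"

    def __post_init__(self) -> None:
        if not (0 < self.b_final <= self.B_init <= 1):
            raise ValueError(
                f"need 0 < b_final <= B_init <= 1, got b_final={self.b_final} "
                f"B_init={self.B_init}"
            )
        if self.f_step <= 0:
            raise ValueError("f_step must be > 0")
        for name in ("s_lis", "p_repr", "consensus_freq", "err_ratio_guard"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("k_bitvec", "k_lis", "iso_kmer_size"):
            v = getattr(self, name)
            if v < 2:
                raise ValueError(f"{name} must be >= 2, got {v}")
        if self.k_bitvec > 15:
            raise ValueError("k_bitvec must be <= 15 (32-bit hash range)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, stamped on artifacts."""
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
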