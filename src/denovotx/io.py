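"""FASTQ / CSV input-output and the core :class:`Read` container.

Qualities are PHRED+33 throughout.  A read's per-base error probabilities are
decoded once at parse time (``err = 10**(-Q/10)``) because the correction
stage consumes probabilities, not integer scores.
"""

from __future__ import annotations

import csv
import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

PHRED_OFFSET = 33
MAX_PHRED = 93  # highest printable PHRED+33 score


def phred_to_err(qual: np.ndarray) -> np.ndarray:
    """Error probabilities from integer PHRED scores (Q=0 -> 1.0)."""
    return np.power(10.0, -np.asarray(qual, dtype=float) / 10.0)


def err_to_phred(err: np.ndarray) -> np.ndarray:
    """Integer PHRED scores from error probabilities, clamped to [0, 93]."""
    with np.errstate(divide="ignore"):
        q = -10.0 * np.log10(np.asarray(err, dtype=float))
    return np.clip(np.rint(q), 0, MAX_PHRED).astype(int)


@dataclass
class Read:
    """A sequencing read: the atomic unit of clustering and correction."""

    read_id: str
    seq: str
    qual: np.ndarray  # integer PHRED, one per base
    err: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=int)
        if self.err is None:
            self.err = phred_to_err(self.qual)
        if not (len(self.seq) == len(self.qual) == len(self.err)):
            raise ValueError(
                f"read {self.read_id!r}: seq/qual/err lengths differ "
                f"({len(self.seq)}/{len(self.qual)}/{len(self.err)})"
            )

    def __len__(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_read(read: Read) -> Read:
    """The read on the opposite strand (qualities reversed alongside)."""
    return Read(read.read_id, reverse_complement(read.seq),
                read.qual[::-1].copy(), read.err[::-1].copy())


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> list[Read]:
    """Parse a (optionally gzipped) PHRED+33 FASTQ file into Reads.

    Raises a ValueError naming the record index on malformed input.
    """
    reads: list[Read] = []
    with _open_text(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
                qual = np.array(rec.letter_annotations["phred_quality"], dtype=int)
                reads.append(Read(rec.id, str(rec.seq).upper(), qual))
        except ValueError as exc:
            n = len(reads)
            raise ValueError(f"malformed FASTQ record at index {n}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path, descriptions: dict[str, str] | None = None) -> None:
    with _open_text(path, "wt") as out:
        for read in reads:
            qual = np.clip(read.qual, 0, MAX_PHRED)
            qstr = "".join(chr(q + PHRED_OFFSET) for q in qual)
            desc = ""
            if descriptions and read.read_id in descriptions:
                desc = " " + descriptions[read.read_id]
            out.write(f"@{read.read_id}{desc}\n{read.seq}\n+\n{qstr}\n")


def filter_short_reads(reads: Iterable[Read], min_len: int) -> list[Read]:
    """Keep reads strictly longer than ``min_len``, preserving order."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [r for r in reads if len(r) > min_len]


def write_cluster_csv(assignments: dict[str, int], path) -> None:
    """Two-column read_id,cluster_id CSV (one row per read, plus header)."""
    if len(assignments) != len(set(assignments)):  # dict keys are unique anyway
        raise ValueError("duplicate read ids")
    with open(path, "w", newline="") as out:
        writer = csv.writer(out)
        writer.writerow(["read_id", "cluster_id"])
        for read_id, cluster_id in assignments.items():
            writer.writerow([read_id, cluster_id])


def read_cluster_csv(path) -> dict[str, int]:
    assignments: dict[str, int] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        header = next(reader, None)
        if header is not None and header[:2] != ["read_id", "cluster_id"]:
            raise ValueError(f"unexpected header {header!r}")
        for row in reader:
            if row[0] in assignments:
                raise ValueError(f"duplicate read id {row[0]!r}")
            assignments[row[0]] = int(row[1])
    return assignments


# ---------------------------------------------------------------------------
# Cluster serialization (versioned JSON; replaces opaque binary intermediates)

CLUSTERS_FORMAT_VERSION = 1


def write_clusters_json(clustering, path, cfg=None) -> None:
    """Serialize a Clustering (see cluster.py) with representatives/orientations."""
    payload = {
        "version": CLUSTERS_FORMAT_VERSION,
        "config_hash": cfg.config_hash() if cfg is not None else None,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "level": c.level,
                "representative_id": c.representative_id,
                "members": [[rid, orient] for rid, orient in c.members],
                "gene_id": c.gene_id,
            }
            for c in clustering.clusters
        ],
    }
    with open(path, "w") as out:
        json.dump(payload, out)


def read_clusters_json(path):
    from .cluster import Cluster, Clustering  # local import to avoid a cycle

    with open(path) as handle:
        payload = json.load(handle)
    if payload.get("version") != CLUSTERS_FORMAT_VERSION:
        raise ValueError(f"unsupported clusters file version {payload.get('version')}")
    clusters = [
        Cluster(
            cluster_id=c["cluster_id"],
            members=[(rid, orient) for rid, orient in c["members"]],
            representative_id=c["representative_id"],
            level=c["level"],
            gene_id=c.get("gene_id"),
        )
        for c in payload["clusters"]
    ]
    return Clustering(clusters)


# ---------------------------------------------------------------------------
# Final transcriptome FASTQ

_HEADER_RE = re.compile(r"gene=(\S+)\s+reads=(\d+)")


def write_transcriptome(transcripts, path) -> None:
    """FASTQ of consensus transcripts; abundance encoded in the header.

    Header format: ``@<transcript_id> gene=<gene_id> reads=<abundance>``.
    """
    with _open_text(path, "wt") as out:
        for t in transcripts:
            if len(t.consensus) != len(t.qual):
                raise ValueError(
                    f"transcript {t.transcript_id}: consensus/quality length mismatch"
                )
            qual = np.clip(np.asarray(t.qual, dtype=int), 0, MAX_PHRED)
            qstr = "".join(chr(q + PHRED_OFFSET) for q in qual)
            out.write(
                f"@{t.transcript_id} gene={t.gene_id} reads={t.abundance}\n"
                f"{t.consensus}\n+\n{qstr}\n"
            )


def read_transcriptome(path):
    """Read back a transcriptome FASTQ written by :func:`write_transcriptome`."""
    from .polish import Transcript  # local import to avoid a cycle

    transcripts = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            m = _HEADER_RE.search(rec.description)
            if m is None:
                raise ValueError(f"missing gene=/reads= fields in header {rec.description!r}")
            transcripts.append(
                Transcript(
                    transcript_id=rec.id,
                    gene_id=m.group(1),
                    consensus=str(rec.seq).upper(),
                    qual=np.array(rec.letter_annotations["phred_quality"], dtype=int),
                    abundance=int(m.group(2)),
                )
            )
    return transcripts
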