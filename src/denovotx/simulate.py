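"""Synthetic long-read generator with per-read truth labels.

Emulates Nanopore-style cDNA/dRNA reads at the study's conditions: random
multi-exon gene models (optionally isoform pairs differing by one internal
exon), per-base substitution / insertion / deletion errors (default 7%
total: 3.5% substitutions, 1.75% insertions, 1.75% deletions, an R9.4-like
profile), and a length model applying geometric 5' truncation (mean 15 nt,
reflecting incomplete 5' recovery of mRNA ends).  Every read carries its
originating gene and isoform, and realized error counts, so clustering and
correction accuracy can be scored exactly.  A synthetic "genome" layout
(one chromosome per gene, 200-nt introns) supports the exon/intron
evaluation module via GTF and truth-PAF output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Read, reverse_complement, write_fastq

BASES = "ACGT"
INTRON_LEN = 200  # synthetic genome: fixed spacer between exons

DEFAULT_SUB_RATE = 0.035
DEFAULT_INS_RATE = 0.0175
DEFAULT_DEL_RATE = 0.0175


@dataclass
class GeneModel:
    """A gene: ordered exon sequences and isoforms as exon-index lists."""

    gene_id: str
    exons: list[str]
    isoforms: list[list[int]]

    def isoform_seq(self, iso: int) -> str:
        return "".join(self.exons[i] for i in self.isoforms[iso])

    def isoform_id(self, iso: int) -> str:
        return f"{self.gene_id}.iso{iso}"

    @property
    def chrom_len(self) -> int:
        n = len(self.exons)
        return sum(len(e) for e in self.exons) + INTRON_LEN * (n - 1)

    def exon_coords(self) -> list[tuple[int, int]]:
        """1-based inclusive genomic coordinates of each exon."""
        coords = []
        pos = 1
        for exon in self.exons:
            coords.append((pos, pos + len(exon) - 1))
            pos += len(exon) + INTRON_LEN
        return coords


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def make_gene(
    n_exons: int,
    exon_len_range: tuple[int, int] = (100, 300),
    seed: int | np.random.Generator = 0,
    gene_id: str = "g0",
    n_isoforms: int = 1,
) -> GeneModel:
    """Random gene with ``n_exons`` exons of uniform base composition.

    With ``n_isoforms`` > 1, isoform 0 contains every exon and isoform j
    drops internal exon j (requires n_exons >= n_isoforms + 1).
    """
    if n_exons < 1:
        raise ValueError("n_exons must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = exon_len_range
    exons = [_random_seq(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_exons)]
    if n_isoforms == 1:
        isoforms = [list(range(n_exons))]
    else:
        if n_exons < n_isoforms + 1:
            raise ValueError("need n_exons >= n_isoforms + 1 for distinct isoforms")
        isoforms = [list(range(n_exons))]
        for j in range(1, n_isoforms):
            isoforms.append([i for i in range(n_exons) if i != j])
    return GeneModel(gene_id=gene_id, exons=exons, isoforms=isoforms)


def make_skipped_exon_pair(
    flank_len: int,
    exon_len: int,
    seed: int | np.random.Generator = 0,
    gene_id: str = "g0",
) -> GeneModel:
    """Two isoforms differing by one internal exon of ``exon_len`` nt."""
    if exon_len < 1:
        raise ValueError("exon_len must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exons = [
        _random_seq(rng, flank_len),
        _random_seq(rng, exon_len),
        _random_seq(rng, flank_len),
    ]
    return GeneModel(gene_id=gene_id, exons=exons, isoforms=[[0, 1, 2], [0, 2]])


@dataclass
class LengthModel:
    """Read-length model: geometric truncation at the read ends.

    ``five_prime_trunc_mean`` is the mean number of template bases lost at
    the 5' end (0 disables truncation); likewise for the 3' end.
    """

    five_prime_trunc_mean: float = 15.0
    three_prime_trunc_mean: float = 0.0

    def sample_window(self, rng: np.random.Generator, template_len: int) -> tuple[int, int]:
        start = 0
        end = template_len
        if self.five_prime_trunc_mean > 0:
            p = 1.0 / (1.0 + self.five_prime_trunc_mean)
            start = int(rng.geometric(p) - 1)
        if self.three_prime_trunc_mean > 0:
            p = 1.0 / (1.0 + self.three_prime_trunc_mean)
            end = template_len - int(rng.geometric(p) - 1)
        start = min(start, template_len - 1)
        end = max(end, start + 1)
        return start, end


@dataclass
class SimulatedRead(Read):
    gene_id: str = ""
    isoform_id: str = ""
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    strand: str = "+"
    tstart: int = 0  # template window (0-based, half-open) before errors
    tend: int = 0


def simulate_read(
    template: str,
    sub_rate: float = DEFAULT_SUB_RATE,
    ins_rate: float = DEFAULT_INS_RATE,
    del_rate: float = DEFAULT_DEL_RATE,
    len_model: Optional[LengthModel] = None,
    seed: int | np.random.Generator = 0,
    read_id: str = "read0",
    gene_id: str = "",
    isoform_id: str = "",
    strand: str = "+",
) -> SimulatedRead:
    """One error-prone read from a transcript template.

    Truncation is applied first, then a per-base edit script: each template
    base is deleted with ``del_rate``, substituted with ``sub_rate``, and
    followed by a random inserted base with ``ins_rate``.  PHRED qualities
    are drawn around the score matching the configured total error rate.
    """
    for r in (sub_rate, ins_rate, del_rate):
        if not (0 <= r < 1):
            raise ValueError("error rates must be in [0, 1)")
    if sub_rate + ins_rate + del_rate >= 1:
        raise ValueError("error rates must sum to < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len_model is None:
        len_model = LengthModel(five_prime_trunc_mean=0.0)
    start, end = len_model.sample_window(rng, len(template))
    window = template[start:end]

    out: list[str] = []
    n_sub = n_ins = n_del = 0
    for base in window:
        if del_rate and rng.random() < del_rate:
            n_del += 1
            continue
        if sub_rate and rng.random() < sub_rate:
            base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
            n_sub += 1
        out.append(base)
        if ins_rate and rng.random() < ins_rate:
            out.append(BASES[int(rng.integers(0, 4))])
            n_ins += 1
    seq = "".join(out)
    if not seq:
        seq = window[:1]
    total_rate = sub_rate + ins_rate + del_rate
    q_center = -10.0 * np.log10(total_rate) if total_rate > 0 else 40.0
    qual = np.clip(
        np.rint(rng.normal(q_center, 2.0, size=len(seq))), 2, 40
    ).astype(int)
    if strand == "-":
        seq = reverse_complement(seq)
        qual = qual[::-1].copy()
    return SimulatedRead(
        read_id=read_id, seq=seq, qual=qual,
        gene_id=gene_id, isoform_id=isoform_id,
        n_sub=n_sub, n_ins=n_ins, n_del=n_del,
        strand=strand, tstart=start, tend=end,
    )


@dataclass
class SimSpec:
    """Design of one simulated dataset (the SI*t-r / MI*t-r scheme).

    ``n_genes`` genes with ``isoforms_per_gene`` isoforms each and
    ``reads_per_transcript`` reads per isoform (``counts`` overrides the
    per-transcript read counts explicitly, in gene-major isoform order).
    """

    n_genes: int = 2
    isoforms_per_gene: int = 1
    reads_per_transcript: int = 10
    counts: Optional[Sequence[int]] = None
    n_exons: int = 3
    exon_len_range: tuple[int, int] = (100, 300)
    sub_rate: float = DEFAULT_SUB_RATE
    ins_rate: float = DEFAULT_INS_RATE
    del_rate: float = DEFAULT_DEL_RATE
    len_model: LengthModel = field(default_factory=lambda: LengthModel(15.0))
    stranded: bool = True  # dRNA-like; False simulates cDNA orientations
    seed: int = 0


@dataclass
class SimulatedDataset:
    reads: list[SimulatedRead]
    genes: list[GeneModel]

    @property
    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "read_id": [r.read_id for r in self.reads],
                "gene_id": [r.gene_id for r in self.reads],
                "isoform_id": [r.isoform_id for r in self.reads],
            }
        )

    def write_fastq(self, path) -> None:
        write_fastq(self.reads, path)

    def write_truth_csv(self, path) -> None:
        self.truth.to_csv(path, index=False)

    def write_transcript_fasta(self, path) -> None:
        with open(path, "w") as out:
            for gene in self.genes:
                for iso in range(len(gene.isoforms)):
                    out.write(f">{gene.isoform_id(iso)} gene={gene.gene_id}\n")
                    out.write(gene.isoform_seq(iso) + "\n")

    def write_gtf(self, path) -> None:
        write_gtf(self.genes, path)

    def write_truth_paf(self, path) -> None:
        write_truth_paf(self.reads, self.genes, path)


def generate_dataset(spec: SimSpec) -> SimulatedDataset:
    """Simulate a full dataset with truth labels, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    n_exons = max(spec.n_exons, spec.isoforms_per_gene + 1)
    genes = [
        make_gene(
            n_exons, spec.exon_len_range, rng, gene_id=f"g{i}",
            n_isoforms=spec.isoforms_per_gene,
        )
        for i in range(spec.n_genes)
    ]
    transcripts: list[tuple[GeneModel, int]] = [
        (gene, iso) for gene in genes for iso in range(len(gene.isoforms))
    ]
    if spec.counts is not None:
        if len(spec.counts) != len(transcripts):
            raise ValueError(
                f"counts has {len(spec.counts)} entries for {len(transcripts)} transcripts"
            )
        counts = list(spec.counts)
    else:
        counts = [spec.reads_per_transcript] * len(transcripts)

    reads: list[SimulatedRead] = []
    for (gene, iso), n_reads in zip(transcripts, counts):
        template = gene.isoform_seq(iso)
        for j in range(n_reads):
            strand = "+" if spec.stranded else ("+", "-")[int(rng.integers(0, 2))]
            reads.append(
                simulate_read(
                    template,
                    spec.sub_rate, spec.ins_rate, spec.del_rate,
                    spec.len_model, rng,
                    read_id=f"{gene.isoform_id(iso)}_r{j}",
                    gene_id=gene.gene_id,
                    isoform_id=gene.isoform_id(iso),
                    strand=strand,
                )
            )
    return SimulatedDataset(reads=reads, genes=genes)


# ---------------------------------------------------------------------------
# Synthetic genome annotation + truth alignments for the evaluation module

def write_gtf(genes: Sequence[GeneModel], path) -> None:
    """GTF of the synthetic gene models (one chromosome per gene, + strand)."""
    with open(path, "w") as out:
        for gene in genes:
            coords = gene.exon_coords()
            for iso, exon_idxs in enumerate(gene.isoforms):
                tid = gene.isoform_id(iso)
                for idx in exon_idxs:
                    s, e = coords[idx]
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                    out.write(
                        f"{gene.gene_id}\tsim\texon\t{s}\t{e}\t.\t+\t.\t{attrs}\n"
                    )


def _aligned_blocks(
    gene: GeneModel, iso: int, tstart: int, tend: int
) -> list[tuple[int, int]]:
    """Genomic (1-based inclusive) exon blocks covered by a transcript
    window [tstart, tend) of isoform ``iso``."""
    coords = gene.exon_coords()
    blocks: list[tuple[int, int]] = []
    offset = 0
    for idx in gene.isoforms[iso]:
        g_s, g_e = coords[idx]
        exon_len = g_e - g_s + 1
        lo = max(tstart, offset)
        hi = min(tend, offset + exon_len)
        if lo < hi:
            blocks.append((g_s + (lo - offset), g_s + (hi - offset) - 1))
        offset += exon_len
    return blocks


def write_truth_paf(reads: Sequence[SimulatedRead], genes: Sequence[GeneModel], path) -> None:
    """Idealized spliced alignments of each read to the synthetic genome.

    One PAF record per read with a ``cs`` tag encoding exon blocks and
    introns (``~gt<len>ag``).  Coordinates come from the read's true
    template window, so the records describe a perfect spliced mapping of
    the error-free template; the strand column carries the gene strand.
    """
    by_gene = {g.gene_id: g for g in genes}
    with open(path, "w") as out:
        for read in reads:
            gene = by_gene[read.gene_id]
            iso = int(read.isoform_id.rsplit("iso", 1)[1])
            blocks = _aligned_blocks(gene, iso, read.tstart, read.tend)
            if not blocks:
                continue
            cs_parts = []
            for b, (s, e) in enumerate(blocks):
                if b > 0:
                    intron_len = s - blocks[b - 1][1] - 1
                    cs_parts.append(f"~gt{intron_len}ag")
                cs_parts.append(f":{e - s + 1}")
            qlen = read.tend - read.tstart
            tstart0 = blocks[0][0] - 1  # PAF is 0-based half-open on target
            tend0 = blocks[-1][1]
            matches = sum(e - s + 1 for s, e in blocks)
            fields = [
                read.read_id, str(qlen), "0", str(qlen), "+",
                gene.gene_id, str(gene.chrom_len), str(tstart0), str(tend0),
                str(matches), str(tend0 - tstart0), "60",
                "cs:Z:" + "".join(cs_parts),
            ]
            out.write("\t".join(fields) + "\n")
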