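"""Exon/intron structure accuracy of spliced reads against an annotation.

Mirrors the splice-structure checker used to validate corrected reads: the
annotation (GTF) and the spliced read alignments (PAF with ``cs`` tags)
are each reduced to four feature classes — introns, intron chains (the
ordered tuple of a transcript's or read's introns), internal exons and
external (first/last) exons — and compared by exact, strand-aware
coordinate identity.  Three ratios are reported per class:

* recall — fraction of unique annotated features found;
* precision — fraction of unique predicted features in the annotation;
* read-precision — fraction of all predicted feature *instances* in reads
  that match the annotation (weights by per-read occurrence).

The read-support sweep re-computes these after discarding predicted
features supported by fewer than t reads, for increasing t.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd

FEATURE_CLASSES = ("introns", "intron_chains", "internal_exons", "external_exons")


@dataclass
class FeatureSet:
    """Unique features per class, plus per-feature read-support counts.

    Coordinates are 1-based inclusive on the genomic strand.
    """

    introns: set = field(default_factory=set)
    intron_chains: set = field(default_factory=set)
    internal_exons: set = field(default_factory=set)
    external_exons: set = field(default_factory=set)
    support: dict = field(
        default_factory=lambda: {cls: Counter() for cls in FEATURE_CLASSES}
    )

    def features(self, cls: str) -> set:
        return getattr(self, cls)

    def add_transcript(self, chrom: str, strand: str,
                       exons: Sequence[tuple[int, int]], count: int = 1) -> None:
        """Register one transcript/read structure given its exon blocks."""
        exons = sorted(exons)
        introns = [
            (chrom, exons[i][1] + 1, exons[i + 1][0] - 1, strand)
            for i in range(len(exons) - 1)
        ]
        for intron in introns:
            self.introns.add(intron)
            self.support["introns"][intron] += count
        if introns:
            chain = tuple(introns)
            self.intron_chains.add(chain)
            self.support["intron_chains"][chain] += count
        for i, (s, e) in enumerate(exons):
            exon = (chrom, s, e, strand)
            cls = "external_exons" if i in (0, len(exons) - 1) else "internal_exons"
            self.features(cls).add(exon)
            self.support[cls][exon] += count


def features_from_gtf(path) -> FeatureSet:
    """Annotated features from a GTF (exon lines grouped by transcript)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_transcript: dict[str, list] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        by_transcript.setdefault(tid, []).append(exon)
    fs = FeatureSet()
    for tid, exons in sorted(by_transcript.items()):
        chrom = exons[0].seqid
        strand = exons[0].strand
        fs.add_transcript(chrom, strand, [(e.start, e.end) for e in exons])
    return fs


_CS_OP = re.compile(r"(:\d+|\*[a-z]{2}|\+[a-z]+|-[a-z]+|~[a-z]{2}\d+[a-z]{2})")


def _exons_from_cs(cs: str, tstart0: int) -> list[tuple[int, int]]:
    """Exon blocks (1-based inclusive target coords) from a cs tag."""
    pos = tstart0 + 1  # current 1-based target position
    exon_start = pos
    exons: list[tuple[int, int]] = []
    consumed = 0
    for m in _CS_OP.finditer(cs):
        op = m.group(0)
        consumed += len(op)
        if op[0] == ":":
            pos += int(op[1:])
        elif op[0] == "*":
            pos += 1
        elif op[0] == "-":
            pos += len(op) - 1
        elif op[0] == "+":
            pass
        elif op[0] == "~":
            intron_len = int(re.search(r"\d+", op).group(0))
            exons.append((exon_start, pos - 1))
            pos += intron_len
            exon_start = pos
    if consumed != len(cs):
        raise ValueError(f"unparseable cs tag: {cs!r}")
    exons.append((exon_start, pos - 1))
    return [e for e in exons if e[1] >= e[0]]


def features_from_paf(path) -> FeatureSet:
    """Predicted features from spliced PAF alignments.

    Each record needs a ``cs`` tag (emitted by spliced mapping); records
    without one are rejected.  The strand column is taken as the feature
    strand of the aligned transcript structure.
    """
    fs = FeatureSet()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(f"PAF line {lineno}: fewer than 12 fields")
            chrom = fields[5]
            strand = fields[4]
            tstart0 = int(fields[7])
            cs = None
            for tag in fields[12:]:
                if tag.startswith("cs:Z:"):
                    cs = tag[5:]
                    break
            if cs is None:
                raise ValueError(f"PAF line {lineno}: missing cs tag")
            try:
                exons = _exons_from_cs(cs.lower(), tstart0)
            except ValueError as exc:
                raise ValueError(f"PAF line {lineno}: {exc}") from exc
            fs.add_transcript(chrom, strand, exons)
    return fs


def extract_features(annotation_gtf, predicted) -> tuple[FeatureSet, FeatureSet]:
    """(annotated, predicted) feature sets from a GTF and a PAF (or GTF)."""
    annotated = features_from_gtf(annotation_gtf)
    predicted_path = str(predicted)
    if predicted_path.endswith((".gtf", ".gff")):
        pred = features_from_gtf(predicted)
    else:
        pred = features_from_paf(predicted)
    return annotated, pred


def feature_accuracy(
    annotated: FeatureSet, predicted: FeatureSet,
    min_support: int = 0,
) -> dict[str, dict[str, Optional[float]]]:
    """Recall / precision / read-precision per feature class.

    ``min_support`` drops predicted features carried by fewer reads before
    scoring.  Precision is None when nothing is predicted in a class.
    """
    out: dict[str, dict[str, Optional[float]]] = {}
    for cls in FEATURE_CLASSES:
        truth = annotated.features(cls)
        support = predicted.support[cls]
        pred = {
            f for f in predicted.features(cls) if support[f] >= min_support
        }
        tp = truth & pred
        recall = len(tp) / len(truth) if truth else None
        precision = len(tp) / len(pred) if pred else None
        total_instances = sum(support[f] for f in pred)
        true_instances = sum(support[f] for f in tp)
        read_precision = (
            true_instances / total_instances if total_instances else None
        )
        out[cls] = {
            "recall": recall,
            "precision": precision,
            "read_precision": read_precision,
        }
    return out


def support_sweep(
    predicted: FeatureSet,
    annotated: FeatureSet,
    thresholds: Iterable[int],
    feature_class: str = "introns",
) -> pd.DataFrame:
    """Accuracy as a function of minimum read support for the predictions."""
    rows = []
    for t in thresholds:
        acc = feature_accuracy(annotated, predicted, min_support=t)[feature_class]
        rows.append({"threshold": t, **acc})
    return pd.DataFrame(rows)


def min_support_for_precision(
    sweep: pd.DataFrame, target: float = 0.95
) -> Optional[int]:
    """Smallest sweep threshold reaching the target precision (None if never)."""
    ok = sweep[(sweep["precision"].notna()) & (sweep["precision"] >= target)]
    if ok.empty:
        return None
    return int(ok["threshold"].min())
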