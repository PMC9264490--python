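"""Multiple sequence alignment substrate for error correction.

An :class:`Msa` stores the gapped rows of one correction block as a numeric
matrix (A,C,G,T -> 0..3, gap -> 4) together with each row's per-base error
probabilities projected onto alignment columns.  The aligner itself is
pluggable; the default engine shells out to ``mafft`` (which preserves the
input row order).  A trivial internal engine handles the degenerate cases
(single row, all rows identical) without a subprocess.

Terminal artifact trimming removes the small mis-aligned islands that
aligners produce at read ends: a terminal block (a run whose internal gaps
are at most 3 columns) shorter than 10 nt that is separated from the rest of
the row by a gap run of at least 20 columns is replaced by gaps, repeatedly,
at both ends of every row.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GAP = 4
_SYMBOLS = "ACGT-"
_CODE = np.full(256, GAP, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_CODE[ord("-")] = GAP


@dataclass
class Msa:
    """Gapped rows over one block of reads, with aligned error probabilities."""

    read_ids: list[str]
    matrix: np.ndarray  # (n_rows, n_cols) int8 codes, 4 = gap
    row_err: np.ndarray  # (n_rows, n_cols) float, NaN at gaps
    row_qual: np.ndarray  # (n_rows, n_cols) float, NaN at gaps
    removed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.removed is None:
            self.removed = np.zeros(self.matrix.shape, dtype=bool)

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row_string(self, i: int) -> str:
        return "".join(_SYMBOLS[c] for c in self.matrix[i])

    def degapped_row(self, i: int) -> str:
        return "".join(_SYMBOLS[c] for c in self.matrix[i] if c != GAP)

    def spanning_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols): True where the column lies between the
        row's first and last non-gap positions (terminal gaps excluded)."""
        nongap = self.matrix != GAP
        any_base = nongap.any(axis=1)
        first = np.where(any_base, nongap.argmax(axis=1), self.n_cols)
        last = np.where(
            any_base, self.n_cols - 1 - nongap[:, ::-1].argmax(axis=1), -1
        )
        cols = np.arange(self.n_cols)
        return (cols >= first[:, None]) & (cols <= last[:, None])


def _project_quals(
    read_ids: list[str],
    gapped: list[str],
    seqs: dict[str, str],
    errs: dict[str, np.ndarray],
    quals: dict[str, np.ndarray],
) -> Msa:
    n_cols = len(gapped[0])
    matrix = np.full((len(gapped), n_cols), GAP, dtype=np.int8)
    row_err = np.full((len(gapped), n_cols), np.nan)
    row_qual = np.full((len(gapped), n_cols), np.nan)
    for i, (rid, row) in enumerate(zip(read_ids, gapped)):
        if len(row) != n_cols:
            raise ValueError("ragged alignment rows")
        codes = _CODE[np.frombuffer(row.encode(), dtype=np.uint8)]
        matrix[i] = codes
        nongap = np.flatnonzero(codes != GAP)
        degapped = row.replace("-", "").upper()
        if degapped != seqs[rid].upper():
            raise ValueError(f"alignment row for {rid!r} does not de-gap to its read")
        row_err[i, nongap] = errs[rid]
        row_qual[i, nongap] = quals[rid]
    return Msa(read_ids=list(read_ids), matrix=matrix, row_err=row_err,
               row_qual=row_qual)


def build_msa(block, engine: str = "mafft") -> Msa:
    """Align one block of oriented reads.

    ``block`` is a list of Read-like objects (read_id, seq, err, qual).
    Engines: ``mafft`` (default) or ``trivial`` (identical sequences only).
    """
    if not block:
        raise ValueError("empty block")
    read_ids = [r.read_id for r in block]
    seqs = {r.read_id: r.seq for r in block}
    errs = {r.read_id: np.asarray(r.err, dtype=float) for r in block}
    quals = {r.read_id: np.asarray(r.qual, dtype=float) for r in block}

    unique = set(seqs.values())
    if len(block) == 1 or len(unique) == 1:
        gapped = [seqs[rid] for rid in read_ids]
        return _project_quals(read_ids, gapped, seqs, errs, quals)
    if engine == "trivial":
        raise ValueError("trivial engine requires identical sequences")
    if engine != "mafft":
        raise ValueError(f"unknown MSA engine {engine!r}")
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")

    with tempfile.TemporaryDirectory() as tmp:
        fa = Path(tmp) / "block.fa"
        with open(fa, "w") as out:
            for i, rid in enumerate(read_ids):
                out.write(f">{i}\n{seqs[rid]}\n")
        proc = subprocess.run(
            ["mafft", "--quiet", "--nuc", "--retree", "2", str(fa)],
            capture_output=True, text=True,
        )
    if proc.returncode != 0:
        raise RuntimeError(
            f"mafft failed on block starting with {read_ids[0]!r}: {proc.stderr[-500:]}"
        )
    order: list[int] = []
    rows: list[str] = []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            order.append(int(line[1:].strip()))
            rows.append("")
        elif line:
            rows[-1] += line.strip()
    if sorted(order) != list(range(len(read_ids))):
        raise RuntimeError("mafft dropped or duplicated sequences")
    gapped = [""] * len(read_ids)
    for idx, row in zip(order, rows):
        gapped[idx] = row.upper()
    return _project_quals(read_ids, gapped, seqs, errs, quals)


def _row_runs(codes: np.ndarray) -> list[tuple[bool, int, int]]:
    """Run-length encode a row into (is_gap, start, end) half-open runs."""
    runs: list[tuple[bool, int, int]] = []
    n = len(codes)
    i = 0
    while i < n:
        j = i
        is_gap = codes[i] == GAP
        while j < n and (codes[j] == GAP) == is_gap:
            j += 1
        runs.append((bool(is_gap), i, j))
        i = j
    return runs


def _terminal_block(runs: list[tuple[bool, int, int]], from_left: bool,
                    max_internal_gap: int = 3):
    """The terminal block (first maximal run-group whose internal gap runs
    are <= max_internal_gap) and the gap run separating it from the rest.

    Returns (base_len, start, end, sep_gap_len) or None if the row has no
    non-gap run on that side.
    """
    seq = runs if from_left else runs[::-1]
    # skip leading terminal gaps
    idx = 0
    while idx < len(seq) and seq[idx][0]:
        idx += 1
    if idx == len(seq):
        return None
    base_len = 0
    start, end = seq[idx][1], seq[idx][2]
    sep = 0
    while idx < len(seq):
        is_gap, s, e = seq[idx]
        if is_gap:
            if e - s > max_internal_gap:
                sep = e - s
                break
        else:
            base_len += e - s
            start, end = min(start, s), max(end, e)
        idx += 1
    return base_len, start, end, sep


def trim_terminal_blocks(msa: Msa, max_block: int = 10, min_gap: int = 20) -> Msa:
    """Remove small mis-aligned terminal islands from every row, in place.

    A terminal block with fewer than ``max_block`` bases separated from the
    rest of its row by a gap run of at least ``min_gap`` columns is replaced
    by gaps; the removal repeats until no such block remains.  Removed cells
    are recorded so corrected output sequences exclude those bases.
    """
    for i in range(msa.n_rows):
        row = msa.matrix[i]
        changed = True
        while changed:
            changed = False
            runs = _row_runs(row)
            for from_left in (True, False):
                tb = _terminal_block(runs, from_left)
                if tb is None:
                    continue
                base_len, start, end, sep = tb
                if base_len < max_block and sep >= min_gap:
                    msa.removed[i, start:end] |= row[start:end] != GAP
                    row[start:end] = GAP
                    msa.row_err[i, start:end] = np.nan
                    msa.row_qual[i, start:end] = np.nan
                    changed = True
                    break  # re-encode runs after any change
    return msa


@dataclass
class ColumnStats:
    counts: dict[str, int]
    consensus_symbol: str
    consensus_freq: float
    mean_consensus_err: float
    n_spanning: int


def all_column_stats(msa: Msa):
    """Vectorized per-column composition over spanning rows.

    Returns (consensus codes, consensus_freq, mean_consensus_err,
    n_spanning, counts matrix of shape (5, n_cols)).  Ties between symbols
    go to the smaller code (A < C < G < T < gap).
    """
    spanning = msa.spanning_mask()
    counts = np.zeros((5, msa.n_cols), dtype=int)
    for code in range(5):
        counts[code] = ((msa.matrix == code) & spanning).sum(axis=0)
    n_spanning = counts.sum(axis=0)
    consensus = counts.argmax(axis=0).astype(np.int8)
    consensus[n_spanning == 0] = GAP
    freq = counts[consensus, np.arange(msa.n_cols)] / np.maximum(n_spanning, 1)
    carries = (msa.matrix == consensus[None, :]) & spanning
    err_sum = np.where(carries, np.nan_to_num(msa.row_err), 0.0).sum(axis=0)
    n_carry = (carries & ~np.isnan(msa.row_err)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_err = np.where(n_carry > 0, err_sum / np.maximum(n_carry, 1), np.nan)
    return consensus, freq, mean_err, n_spanning, counts


def column_stats(msa: Msa, col: int) -> ColumnStats:
    """Composition of one alignment column (terminal gaps excluded)."""
    if col >= msa.n_cols:
        raise IndexError(col)
    consensus, freq, mean_err, n_spanning, counts = all_column_stats(msa)
    return ColumnStats(
        counts={s: int(counts[i, col]) for i, s in enumerate(_SYMBOLS)},
        consensus_symbol=_SYMBOLS[consensus[col]],
        consensus_freq=float(freq[col]),
        mean_consensus_err=float(mean_err[col]),
        n_spanning=int(n_spanning[col]),
    )
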