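# Methods

## Model and assumptions

`denovotx` assumes that long cDNA/dRNA reads from one gene share most of
their k-mer content despite per-base error rates around 5–10%, that reads
from different genes share little beyond chance, and that reads from two
isoforms of one gene differ by the *spacing* of their shared k-mers rather
than by their presence. These three observations drive the three decision
statistics of the pipeline:

* **Bit-vector score** — |shared k-mers| / max(k-mer count), k = 6. With a
  6-mer alphabet of 4096 and per-base accuracy ~0.93, two reads of the same
  ~1 kb transcript share roughly (0.93²)⁶ ≈ 65% of their 6-mers, while
  unrelated reads share mostly the chance background; the decreasing
  threshold schedule (0.40 → 0.20) lets confident pairs cluster early and
  noisy ones late.
* **LIS score** — reads are reduced to exact shared k-mer matches with
  positions (k = 10 at the gene stage); the longest chain strictly
  increasing in both coordinates is found, and the score is the fraction of
  the shorter read covered by the chain's k-mer intervals. This tolerates
  indel-induced position drift that defeats fixed-offset comparison.
* **Gap-difference variance** — along the chain, d_i = Δp1_i − Δp2_i is
  ~0 between reads of the same isoform (indels contribute ±1–2) but jumps
  once by the exon length L between isoforms differing by an internal
  exon. With m chain gaps the population variance is ≈ L²(m−1)/m², so
  separability improves with exon length and degrades with chain density —
  which is why the minimal separable exon is tens of nt, not zero.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `k_bitvec` | 6 | k-mer size of the presence bit-vector (≤ 15 so hashes stay in 32-bit range) |
| `k_lis` / `iso_kmer_size` | 10 / 11 | chain k-mer size at the gene / isoform stage |
| `B_init`, `b_final`, `f_step` | 0.40, 0.20, 0.05 | bit-vector threshold schedule; a 0.0 (LIS-only) pass always follows |
| `s_lis` | 0.20 | LIS score floor, fixed across all passes |
| `p_repr` | 0.15 | representative = member at floor(0.15·N) of the descending-length ranking |
| `iso_score_threshold` | 0.30 | LIS floor when splitting isoforms |
| `iso_max_variance` | 25 | gap-difference variance above which reads are declared different isoforms |
| `block_size` | 200 | reads per correction block |
| `consensus_freq` | 0.60 | column-consensus frequency needed to correct |
| `err_ratio_guard` | 1/3 | a read base with error ≤ guard × mean consensus error is trusted over the consensus |
| `min_cluster_reads` | 5 | clusters need **more** than this many reads to be corrected/retained |
| `min_read_len` | 150 | reads this long or shorter are dropped up front |

## Algorithmic choices

* **Greedy assignment** — a read joins the *first* cluster (in creation
  order) passing both thresholds, not the best-scoring one; merging after
  each pass is transitive via union–find with strand parity, and the
  surviving cluster keeps the smaller id. Length ties anywhere break by
  read id. These make the whole pipeline byte-deterministic.
* **LIS** — triplets sorted by (p1, p2); equal-p1 groups are processed in
  descending p2 during the patience pass so a k-mer repeated at one
  position can never chain with itself; among equally long chains the
  lexicographically smallest in (p1, p2) is reconstructed greedily.
  Verified against an exhaustive-subset oracle on >1000 random instances.
* **Variance** — population (not sample) variance, 0 for chains with fewer
  than two gaps; small chains would otherwise blow up at n = 2.
* **MSA engine** — pluggable; the default shells out to `mafft` (order
  preserving, gap-free on identical input). Degenerate blocks (single or
  identical sequences) are aligned trivially without a subprocess.
* **Column statistics** — computed over *spanning* rows only (terminal
  gaps excluded), matching the idea that a read should only be corrected
  where other reads actually align. Columns spanned by fewer than 3 rows
  never correct and are excluded from block consensi: with one or two
  voters the "consensus" is noise, and such columns are overwhelmingly
  spurious terminal pile-ups of insertion errors.
* **Consensus qualities** — per column, the mean PHRED of the bases in the
  column, rounded and clamped to [0, 93]. Bases inserted into a read
  during correction get the column's mean consensus PHRED; substituted
  bases keep their original quality.
* **Block realignment** — block consensi are re-aligned and vote per
  column with their per-base *read support* (how many reads carried that
  base); rows lacking a base vote gap with their whole block's read count.
  A 2–3-row alignment has no meaningful majority, so weighting by the
  underlying read evidence is what makes multi-block clusters reach the
  same consensus accuracy as single-block ones. Polishing merges use the
  same weighted vote; a merged transcript's consensus is built from its
  member cluster consensi (the data polishing receives), not by re-aligning
  all reads.
* **Gene absorption** — when transcript clusters from different genes
  merge, every transcript of the gene with fewer transcripts moves to the
  gene with more; ties go to the smaller gene id; merges are processed in
  ascending cluster-id order so cascades are deterministic.
* **Ambiguous bases** — hashed as 'A' (hashing needs a 2-bit alphabet and
  Ns are rare after length filtering) but preserved verbatim in output
  sequences. PHRED offset is fixed at +33.
* **Trimming order** — terminal-island trimming runs before per-column
  correction, so mis-aligned read ends cannot distort column consensi.
* **Final 0.0 pass** — the LIS threshold `s_lis` remains enforced when
  singletons and representatives are compared with the bit-vector gate
  open.
* **Abundance** — the read count of the final merged cluster; reads in
  clusters at or below `min_cluster_reads` are emitted uncorrected and not
  counted toward any transcript.

## The simulator

The generator emulates the study conditions rather than a specific
basecaller: uniform-composition exons (single- and multi-isoform genes;
skipped-exon pairs with configurable internal-exon length), per-base edit
errors at 7% total by default (3.5% substitution, 1.75% insertion, 1.75%
deletion — an R9.4-like cDNA profile), and geometric 5′ truncation with
mean 15 nt reflecting incomplete 5′ recovery of mRNA ends. Qualities are
drawn around the PHRED score matching the configured error rate (σ = 2,
clamped to [2, 40]). Each read records its gene, isoform, template window
and realized error counts. A synthetic genome (one chromosome per gene,
fixed 200-nt introns) with a GTF and idealized spliced "truth" alignments
(PAF with `cs` tags, strand column carrying the gene strand) closes the
loop for the feature-accuracy module.

What the simulator does **not** model: homopolymer-biased errors,
quality-error correlation within a read, chimeras/adapters, the empirical
read-length distribution of real runs, and sequence homology between
genes (gene templates are independent random sequences). Passing tests
therefore demonstrate the algorithms' correctness and their behavior under
calibrated error/truncation levels, not performance on real libraries,
where inter-gene homology and systematic errors make clustering and
correction strictly harder.

## Scale of the shipped experiments

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes at which the measured quantities stabilize: the
isoform-separability sweep uses 50 reads per isoform across exon lengths
25–145 nt (400-nt flanks), and the recovery experiment uses 20
single-isoform genes with log-uniform read counts between 5 and 500
(~2.5k reads, transcript lengths ~0.75–1.2 kb). On one CPU the full suite
takes about 3 minutes, dominated by the recovery experiment's MSA stages.

## Known limitations

* Isoforms differing only at the 5′/3′ termini are confounded with
  truncation and are not separated.
* The gap-variance criterion needs chains of ≥ 3 matches; very short or
  very noisy reads fall back to best-LIS assignment and can land in the
  wrong isoform cluster.
* Consensus accuracy at the extreme 5′ end is limited by truncation
  coverage; columns with fewer than 3 spanning reads are dropped from the
  consensus.
* Feature comparison is exact-coordinate and strand-aware; alignments
  without `cs` tags are rejected rather than approximated.
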