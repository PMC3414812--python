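# Methods

## The evaluation model

The toolkit treats aligner evaluation as a measurement problem with two
instruments:

* **Concordance** (no truth available): for a pair of aligners run on the
  same reads, the union of reads aligned by at least one of them is
  partitioned into four classes — same location by both (1), different
  locations (2), aligned only by the first (3), only by the second (4).
  Percentages use the union size as denominator, so the classes always sum
  to 100 %. "Same location" means same chromosome, identical leftmost
  0-based coordinate (within an optional `tolerance`, 0 by default) and
  same strand (`require_strand=True` by default). The tolerance exists for
  trimmed-read comparisons, where 5'-end trimming legitimately shifts the
  leftmost coordinate. Suppressed (multi-hit) and unaligned reads are both
  "not aligned". Swapping the pair's order swaps classes 3 and 4 and
  preserves everything else.

* **Accuracy** (simulated truth): an alignment is true iff chromosome,
  leftmost position (within tolerance) and strand equal the origin the
  read was generated from. `false_rate = false / aligned`: the denominator
  is reported reads only, because a suppressed read makes no claim. The
  aligned percentage uses all reads as denominator.

## The exhaustive oracle aligner

Production aligners are heuristic; the oracle is not. For each read it
enumerates every location on both strands with Hamming distance at most
the mismatch budget (reference N mismatches everything), then reports by
one of the study's two conventions:

* `random_one` — one hit drawn uniformly among the minimum-distance hits.
  The tie-break RNG is derived per read from (global seed, read ID), so
  results are independent of read order.
* `unique_only` — report the hit only when the read's multiplicity is 1,
  otherwise suppress. Multiplicity counts every within-budget hit by
  default (`unique_scope="budget"`): a read with one perfect and one
  1-mismatch location is *suppressed*, the strict reading of "can be
  aligned to multiple locations". `unique_scope="best"` switches to
  counting only the best stratum, since either convention is defensible.

Implementation: the read is split into `budget + 1` near-equal chunks; at
any within-budget location at least one chunk matches the reference
exactly (pigeonhole), so exact chunk lookup in a genome substring index
followed by Hamming verification at each candidate enumerates the complete
hit set. This is algebraically identical to a full sliding-window scan and
is verified against an independent naive numpy scan in the test suite. The
index costs O(genome × distinct chunk lengths) memory, which is the right
trade-off at the 100-kb–1-Mb scale the toolkit targets; it is rebuilt per
`oracle_align` call.

Two consequences of exhaustiveness are analytic and anchor the acceptance
checks: (a) when the budget ≥ the simulated mismatch count, the origin is
always a hit, so `random_one` aligns 100 % of simulated reads; (b) a
uniquely alignable read must sit at its origin, so `unique_only` has
exactly zero false alignments. For reads wholly inside a k-copy exact
repeat, `random_one` picks the wrong copy with probability (k−1)/k.

Oracle MAPQ is a convenience convention (37 = single within-budget hit,
0 = ambiguous), mirroring the familiar unique/ambiguous semantics of
backtracking aligners; it carries no probability calibration.

## Synthetic references and what they do (not) emulate

`generate_synthetic_genome` draws i.i.d.-uniform A/C/G/T and pastes each
repeat unit `copies` times at uniformly drawn non-overlapping positions,
mutating each copy at the per-base `divergence` rate. Every footprint is
recorded, so repeat structure is exact by construction. At 50-bp reads and
100-kb backgrounds, chance off-target hits within 2 mismatches are
vanishingly rare (expected count ≈ 2·10⁵ windows × P(≤2 mismatches in 50
random bases) ≈ 10⁻²⁰), so the repeat-free genome behaves as "every window
unique".

This emulates the two study conditions — mostly-unique exon-like targets
and repeat-rich CpG-island-like targets — but not real genomes: no base
composition bias, no repeat families with internal structure, no
heterozygosity, no sequencing-machine error profiles (mismatch counts are
exact, no indels), single-end reads only. Passing tests therefore show the
*scoring machinery* and the analytic properties are correct; they do not
predict absolute performance numbers of heuristic aligners on real data.

Region selection implements the repetitive criterion: at least
`min_fraction` (default 0.25) of region bases repetitive AND at least one
repetitive run of `min_run` (default 50) bp. Runs are measured after
merging adjacent/overlapping annotation intervals and are clipped to the
region. Both thresholds are monotone: tightening either never adds a
region.

## Simulation parameters

| parameter | default | why |
|---|---|---|
| read length | 50 bp | the simulated-data read length of the study design |
| mismatches per read | 1 or 2 | SNV-like vs error-pair scenarios |
| HIGH quality band | Phred 30–40 | confident calls (error ≤ 10⁻³) |
| LOW quality band | Phred 5–15 | error-like calls (error 3–30 %) |
| mismatch budget | 2 | the "at most two mismatches" setting |
| trim threshold | Q > 20 | strict reading: Q ≤ 20 trimmed, Q = 21 stops |
| min trimmed length | 24 bp | discard shorter reads |
| max Ns | 2 | counted on the trimmed read (configurable to pre-trim) |
| mapability k | 35 | the 35-bp uniqueness window |

Reads never span region boundaries and windows containing N are redrawn,
so the injected mismatch count is exact. Mismatch offsets are uniform over
the read (chi-square checked at n = 50,000). Start positions are uniform
over all valid (region, offset) pairs, i.e. regions are weighted by the
number of windows they contain; strands are drawn per read by default,
with a forward-only mode.

`origin_pos` is always the leftmost forward-strand coordinate (SAM POS
convention), and mismatch offsets are read coordinates after reverse
complementing, i.e. what an aligner sees. The trimmer updates `origin_pos`
for kept reads (5'-trim shifts plus-strand origins, 3'-trim shifts
minus-strand origins) so truth comparison stays exact after trimming.

## Mapability

Per position, the score is 1/c for the k-mer starting there occurring c
times, 0 for c > 4, i.e. the value set {1, 0.5, 1/3, 0.25, 0}. Counting is
over the forward text only by default; whether uniqueness should fold in
reverse-complement occurrences is genuinely ambiguous, so a
`fold_strands` flag provides the folded variant (palindromic k-mers not
double-counted) without asserting either as canonical. k-mers containing N
score 0. A region's positions are the windows lying fully inside it; a
region is "completely unique" when all of them score 1. Cohort mean and
median pool per-position scores across regions.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere; 1-based only inside SAM
  files (pysam converts on both paths).
* Trimming is idempotent by construction (kept reads start/end above the
  threshold), and the discard accounting conserves counts.
* SAM records lacking an NM tag when NM filtering is requested are kept,
  exempted from the filter, and counted — silently dropping them would
  bias concordance against aligners that omit the tag.
* Secondary/supplementary SAM records are ignored (counted), so exactly
  one record exists per read.
* `classify_pair` raises on disjoint read universes (almost certainly
  mismatched inputs); `score_accuracy` raises on an aligned read missing
  from the truth table.
* Empty region lists, empty FASTQ input, fully-trimmed reads, reads longer
  than every chromosome, and impossible repeat placements all fail with
  specific errors rather than degenerate numbers.

## Problem sizes

The shipped presets and acceptance script use 100-kb genomes, 2,000 reads
per scenario (5,000 for the (k−1)/k binomial check, 50,000 for the
uniformity goodness-of-fit), sizes at which the exhaustive oracle and the
brute-force verification oracles run comfortably on one CPU while leaving
the analytic properties unchanged — they hold at any scale.

## Known limitations

* Gapped alignment, paired-end reads, and adapter trimming are out of
  scope; the mismatch-only model matches the evaluation design, not
  real aligner feature sets.
* The oracle's "best = fewest mismatches" criterion matches
  mismatch-budget aligners; quality-weighted scoring models
  (Novoalign-style alignment scores) are not reproduced, so the oracle
  cannot emulate their characteristic disagreements.
* Real-data concordance studies (e.g. between heuristic aligners on
  Illumina runs) are supported via SAM ingestion but obviously require
  those aligners' outputs; the built-in pipeline only exercises the
  oracle.
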