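# Methods

## Model

A spliced intron persists briefly as a lariat whose loop is closed by a
2′–5′ phosphodiester bond between the 5′ splice site and the branch-point
base. Reverse transcriptase can traverse this bond, producing cDNA in
which intronic sequence immediately upstream of the branch point is
followed by the intron's 5′ end; it also mutates the branch-point base
frequently and occasionally skips it. `lariatscan` detects these
junction-spanning reads by exhaustive enumeration rather than inference:
every intronic base is a candidate branch point, each candidate defines
one diagnostic signature, and reads that failed conventional alignment
are matched against the signature set.

### Signature construction

For an intron of length *L* and read length *k*, the signature for
candidate position *p* (1-based, transcript orientation) is

```
last min(k−1, p−1) bases of intron[1..p−1]  +  intron[p]  +  first min(k−1, L) bases of the intron
```

Candidates iterate from the 3′ end to position 1. Position 1 has an empty
5′ segment; it is emitted (the enumeration is exhaustive) but flagged
`degenerate`, and any junction-overlap requirement ≥1 makes it inert.
In adenine-only mode (the default for large, degenerate-branch-site
genomes such as human) only adenines are candidates. Signatures containing
N are emitted but flagged; the matcher counts N as a mismatch on either
side, so they can never produce spurious perfect hits.

Exon-skipping signatures are built for every ordered intron pair
(*i* < *j*) of a transcript — `(I−1)·I/2` events for *I* introns. The
construction concatenates the upstream intron in front of the downstream
intron, iterates branch-point candidates over the downstream intron only,
and takes the 3′ segment from the upstream intron's 5′ end. When the
branch point lies within *k*−1 bases of the downstream intron's 5′ end the
5′ segment therefore extends into the *upstream intron's 3′ end* — a
deliberate reproduction of the original construction. Biologically that
context is the skipped exon, so `build_skipping_signatures` accepts an
`intervening` map that substitutes the true exon sequence instead; the
default keeps the intron-concatenation form. Simulated skipping reads use
the true exonic context, so reads whose 5′ arm crosses into the exon do
not match the default database — a realistic, documented loss channel.

### Matching

The matcher's contract is ungapped, fully contained placement with
Hamming distance ≤ *m* (brute force over all offsets defines the
semantics and serves as the test oracle). The production path uses the
pigeonhole principle: any valid placement contains at least one exact
seed of length `⌊len(read)/(m+1)⌋` among *m*+1 disjoint seeds, so exact
seed lookup plus verification is complete. For small reference sets the
references are indexed; above 2 Mb of reference the read seeds are
indexed and the references scanned once — both paths are tested for exact
equivalence with the brute-force scan.

Classification is staged: genome (≤3 mismatches, both orientations —
the genome is double-stranded), then exon–exon junctions (sense-only for
strand-specific libraries), then the lariat database (≤1 mismatch,
sense-only). A read is assigned to the first stage where it places.
Multi-locus reads (several genomic placements, or several distinct
reference sequences in a database stage) remain in that stage's partition
but are flagged ambiguous and excluded from all downstream tables, so the
four partitions are a disjoint cover of the input. Reads hitting both a
canonical and a skipping signature sequence are ambiguous by this rule and
are dropped and counted separately.

### Branch-point calling

Hits become per-(intron, offset) observations; a read whose surviving
hits imply more than one (intron, offset) interpretation is dropped.
Observations within `cluster_gap` (default 1) bases are chained into
clusters — RT base-skipping puts support exactly 1 base 5′ of the true
branch point, which is what this absorbs. The cluster representative is
the highest-read member unless the top two members differ by fewer than
`tie_delta` (default 10) reads, in which case the 3′-most of those two is
chosen; the tie rule is applied to the top two members of a chain (the
published description does not specify whether all pairwise neighbors are
compared; the top-two reading is the minimal one consistent with it).
Clusters with total support < `min_reads` (default 3) are discarded;
`min_reads` applies to cluster support because RT errors scatter reads
over adjacent offsets (a strict per-offset variant is available). The
best-supported cluster yields the primary branch point; remaining
clusters are alternates, necessarily > `cluster_gap` bases away.
Non-adenine observations arise only in all-bases mode and stay in the
calls with their base recorded. A skipping call is labeled
`bp_shared_with_canonical` when its branch point equals the downstream
intron's canonical primary — reported as a derived statistic, not
enforced.

Stringent filtering (human preset) additionally removes antisense hits,
hits whose single mismatch is not exactly at the branch-point base
(zero-mismatch hits pass), and hits overlapping the lariat junction by
fewer than 10 bases on either side.

The consensus matrix collects −flank..+flank windows (default ±5) around
canonical primary branch points, excluding windows clipped by intron
bounds, and reports per-column probabilities plus information content
`Σ p·log₂(p/q)` against a 30% GC background (A=T=0.35, C=G=0.15) — the
composition adjustment appropriate for an AT-rich genome.

### Splicing statistics

`SE = JR/(JR+EI)`: JR counts uniquely junction-mapped reads overlapping
the exon–exon boundary by ≥6 bases per side; EI counts uniquely
genome-mapped reads straddling the *upstream* exon/intron boundary by the
same margin (the downstream boundary is not counted, and the same overlap
threshold is reused for EI since no separate value is specified). SE is
implemented as a bounded proportion; the unbounded ratio JR/EI is
available behind a flag. The Cochran–Mantel–Haenszel χ² statistic (1 df)
is computed without continuity correction by default (a correction flag
exists since reference implementations differ); strata with a zero margin
or total ≤1 contribute nothing, and an all-degenerate table yields NaN
with a warning. Storey q-values estimate π₀ on the λ grid 0.05..0.95
(step 0.05) with a cubic polynomial trend evaluated at λ=0.95 — the
closest dependency-free analogue of the reference smoothing-spline
estimator — clamped to (1/m, 1]; Benjamini–Hochberg is the alternative.
RPKM adds 10⁻⁵ to avoid logs of zero.

## Simulator

`simulate` emulates the study conditions: 200 genes with 2–5 exons
(uniform), exon lengths 80–300, intron lengths log-uniform over 30–500
(intron length distributions are short-dominated — in fission yeast about
a third of introns are shorter than a 49-base read — and the log-uniform
draw reproduces that while spanning the full range), introns starting GT
and ending AG with a planted CTAAC branch site whose adenine sits at a
uniform 8–16 (median 12) bases from the 3′ end, genome GC 36%. Reads are
single-end, strand-specific, 49 bases. Lariat reads run along the lariat
loop: *u* bases ending at the branch point followed by the intron's first
*v* = 49−*u* bases; the branch-point base is mutated with probability 0.2
and deleted with probability 0.02. When *u* exceeds the available loop
(branch-point offset) the read wraps around the loop and crosses the
junction twice, making it unmappable — this read-containment mechanism,
not insert-size modeling, is what produces the short-intron detection
bias. Default read-class fractions are 40% mRNA / 20% pre-mRNA / 40%
lariat (debranching-deficient cells are strongly lariat-enriched); the
recovery harness instead fixes 10 lariat reads per intron so that nearly
every intron meets the ≥3 error-free-read condition, with a 20k-read
mRNA/pre-mRNA background. Skipping lariat reads are Binomial(n, 0.05) per
intron pair and use the true exonic upstream context.

The two-condition differential-splicing check simulates JR/EI counts
directly (per-intron baseline SE uniform 0.7–0.95, Poisson depth 60,
binomial splitting, 2 paired replicates; condition B halves the splicing
probability of 30 of 300 introns) — the property under test is the
CMH/q-value machinery, not the aligner.

What the simulator does **not** model: sequencing errors off the branch
point (substitution machinery exists but defaults to the RT effects
only), quality scores, insert-size distributions, paired ends, intron
retention, overlapping genes, repetitive sequence, and annotation errors.
Passing recovery tests therefore demonstrates the correctness of the
enumeration/matching/clustering machinery under the stated error model,
not performance on real libraries, where adaptor contamination, repeats
and expression skew dominate.

## Numerical and design choices

- Coordinates are 1-based inclusive internally; BED export is 0-based
  half-open.
- Tie-breaks: within one reference, a read's placements are ranked by
  fewer mismatches then smaller offset; between clusters of equal
  support, the 3′-most representative wins.
- Canonical candidates include the intron's terminal base (the acceptor
  G) in all-bases mode; adenine-only mode excludes it naturally.
- `evaluate_recovery` scores introns of at least read length with ≥3
  error-free lariat reads (not mutated, not skipped, not wrapped), the
  condition under which exact recovery is expected; the acceptance runs
  use 200 genes (~500 introns, ~25k reads), sized to finish in seconds
  on one CPU while keeping the short-intron class ≥30 introns.
- Determinism: all randomness flows through `numpy.random.default_rng`
  seeds; pipeline outputs are a pure function of (inputs, config, seed),
  recorded with input checksums in `manifest.json`.

## Known limitations

- The internal matcher is exhaustive-exact but pure Python; for real
  libraries (10⁸ reads, GB-scale databases) the SAM ingestion path
  (`ingest_external_alignments`) exists to consume an external aligner's
  output instead.
- Chunked database output supports parallelization in principle, but
  whole-genome sliding-window databases and the full human database are
  out of scope.
- EI counting uses genomic placements from the internal genome stage;
  spliced (gapped) alignment is not performed anywhere.
- The q-value π₀ estimate uses a cubic polynomial rather than a
  smoothing spline; on small p-value sets the two can differ slightly
  (both are monotone and conservative-clamped).
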