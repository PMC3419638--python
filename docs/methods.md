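# Methods

## Problem setting

A BAC library sample is characterised by sequencing both ends of each
clone insert and aligning the reads to a related reference genome. A
clone whose two ends land on one reference chromosome, pointing at each
other, separated by a distance compatible with the insert, marks a locally
collinear (microsyntenic) region; every other configuration indicates a
rearrangement, a missing end, or an ambiguous placement. Because the two
genomes accumulate insertions and deletions independently, the reference
span of a concordant clone differs from its insert size, and the summed
difference over many clones estimates net genome expansion or contraction
between the species. This package implements that whole analysis as a
reusable pipeline plus a generator of synthetic datasets with planted
ground truth.

## Read QC

Vector trimming removes the longest read prefix/suffix that continues a
vector substring for ≥ `vector_min_seed` (default 12) bases with at most
`vector_max_mismatch` (default 0) mismatches. A vector match in the read
interior keeps the longer flank; interior detection requires a match of
at least twice the seed length, because a 12 bp exact match arises by
chance in kilobase-scale reads against a multi-kilobase vector, whereas
genuine interior carry-over is tens of bases.

Quality trimming keeps the largest segment in which every sliding window
(`trim_window` = 20 bases) has mean quality ≥ `trim_min_mean_q` (20);
survivors shorter than `trim_min_length` (100 bp) are rejected. Windows
that straddle the segment edge average across it, so the kept segment can
exceed a planted high-quality core by up to one window length per side —
tests that need exact boundaries set the threshold equal to the core
quality. FASTA input without a quality channel is treated as uniform Q40.
Both operators are idempotent.

Organelle screening flags a read when some alignment against an organelle
genome has E ≤ 1e-20 *and* covers ≥ 80 % of the read (`organelle_min_coverage`,
per single hit). A clone is contaminated if either end is flagged —
contamination is reported per clone, matching how plastid carry-over is
quoted for BAC libraries — and contaminated clones are excluded from
reference mapping.

## Mapping

The built-in mapper indexes the reference with exact k-mers
(`kmer_size` = 15, sorted-array index over the 2-bit-packed concatenated
genome; k-mers spanning chromosome boundaries are masked). For each read
and strand, seed matches define candidate diagonals; on each diagonal the
best-scoring ungapped segment (match +1, mismatch −3, maximum-scoring
subarray) becomes a hit. Raw scores convert to a BLAST-style expectation
`E = K·m·n·exp(−λS)` with fixed λ = 1.28, K = 0.46 (configurable); hits
with E above `evalue_max` (1e-20) are dropped, and only the best hit per
(chromosome, strand, 10 kb window) is kept to emulate one-HSP-per-locus
reporting. Gapped alignment is deliberately absent: the synthetic error
model is substitution-only, and conserved tracts in the synthetic
reference are contiguous at read scale (see below).

`brute_force_map` is the independent oracle: an exhaustive full-read
window scan of both strands. The exact-match path uses plain substring
search; the mismatch-tolerant path is the naive O(N·L) scan and is meant
for genomes of at most a few megabases.

Repeat masking aligns each library consensus (both strands) against the
read with the same seed-and-extend machinery; segments scoring ≥
`repeat_min_score` (60) are kept, same-family overlaps merged, and
cross-family conflicts resolved by score (ties: longer interval, then
lexicographic family name), trimming the loser to its uncovered remainder
so the final annotation set is non-overlapping. Reads more than half
repeat-masked (`repeat_exclusion_fraction` = 0.5) are withheld from
synteny mapping; the published analysis excludes "repetitive" ends without
stating a threshold, so the 0.5 cutoff is this package's own configurable
choice, and a clone with an excluded end is classified as if that end were
unaligned.

## Synteny classification

Orientation of a same-chromosome pair is defined from the upstream hit U
(smaller start) and downstream hit D: opposite-in is U:+ / D:−, opposite-out
is U:− / D:+, same otherwise. Span is the *outer* span
(max end − min start), interpreted as the projected insert size; the
concordant window is closed on both ends, 20,000 ≤ span ≤ 300,000 bp,
bracketing the insert-size range. Among all same-chromosome end pairings,
the one maximising the score sum wins; ties prefer a concordant pairing,
then the smaller span, then the lexicographically smaller chromosome.
C6 (different chromosomes) is assigned only when no same-chromosome
pairing exists at all — a higher-scoring cross-chromosome combination does
not override a same-chromosome one unless `allow_cross_chrom_override` is
set. Span-band combinations outside the published grid (spans < 20 kb;
opposite-out ≤ 300 kb) are reported as X1–X4, never folded into C1–C6.

The count table satisfies two identities on any input: class counts sum
to the clone count, and the aligned-end total is twice the both-ends
classes plus once the single-end classes. With the published counts
(42, 1, 16, 12, 15, 9, 10, 65, 22) these give 265 aligned ends and 192
clones. The published text and table disagree on the numbering of the
single-end classes (text: class 8 single / class 9 multiple; table grid:
C7 single, C8 multiple, C9 none); this package follows the table grid.

## Expansion statistics

One region per concordant clone: insert size vs. placement outer span.
A tie (delta 0) counts as contracted, so "expanded" strictly means larger.
The net expansion percent is the total-ratio form
`100·(Σref − Σquery)/Σquery`, reported to two decimals alongside the
integer rounding (per-region mean and reference-denominator variants were
considered and rejected as defaults because the total-ratio is the only
form whose numerator equals the printed grand-total delta). On the
published per-chromosome sums this gives 29.9652… % → 29.97; the printed
headline is 29 %. Fold coverage is `n_clones·mean_insert/genome_size`,
reported at 760, 930 and 580 Mb monoploid genome sizes (the two ends of
the cytometric range and the revised, expansion-corrected estimate).

## Repeat ledger

Annotations carry a leaf family resolving to a path in a rooted taxonomy
(Transposable Element → RNA/DNA transposon → … → Copia, etc.). Counts and
base totals roll up the tree; each node is expressed as a percent of all
read bases and of all repeat bases. Internal nodes may hold bases not
attributed to any child — the published table itself has Copia + Gypsy
(136,570 bp) below the LTR total (136,899 bp) — so children are never
forced to sum to their parent; the invariant is parent ≥ sum(children).
The total-read-base denominator is an explicit input (the pipeline
supplies the post-trimming base total). Two LTR fractions circulate with
different denominators (85.2 % of transposable-element bases vs ~83–84 %
of all repeat bases); both are derivable from the ledger and neither is
"corrected".

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
with every draw flowing from one master seed through named substreams
(same config + seed ⇒ byte-identical files).

* **Query genome** — i.i.d. background at `gc_content` (0.44) with repeat
  copies planted at exponentially spaced positions to a target density
  (`repeat_density` = 0.45 of genome bases, matching the ~45 % repeat
  content of the reads), each copy diverged by a uniform 2–15 %
  substitution rate. Consensus lengths and base-share weights follow an
  LTR-dominated grass landscape (Copia/Gypsy ≈ 85 % of repeat bases, DNA
  transposons ≈ 11 %). Because detection loses diverged copy ends, the
  *measured* masked fraction of reads runs a few points below the planted
  density.
* **Reference genome** — the query tiled into blocks (`block_length`
  400 kb) scaled by truncated-normal factors (mean 1.30, sd 0.15, clipped
  to [0.1, 10]), 5 % of blocks inverted, 5 % translocated. Scaling
  inserts or deletes contiguous random tracts (exponential sizes, mean
  5 kb) at uniform positions: length changes in real genomes accumulate
  as repeat/indel tracts between conserved stretches, and this keeps
  sub-kilobase reads alignable without gaps while block spans scale. The
  block map records exact query↔reference correspondence.
* **Clones and reads** — insert sizes from a truncated normal, mean
  125 kb, sd 35 kb, bounds [29, 293] kb. The sd is a calibration choice:
  the published distribution is summarised only by mean/min/max and the
  fraction of inserts above 90 kb (~88 %), and 35 kb reproduces that
  fraction (40 kb does not). Reads are normal(944, 150) bp, floored at
  312 bp and capped at half the insert; forward from the 5′ end, reverse
  as the reverse complement of the 3′ end; quality flat at Q45 then
  decaying linearly to Q25 over the final 40 %; substitution errors at
  0.5 %/base (no indels, keeping the brute-force oracle exact).
* **Contamination** — each clone independently replaced by an insert from
  a circular 150 kb organelle genome with probability 0.005.
* **Planted classes** — for classifier-recovery experiments, a separate
  generator plants read pairs directly at reference coordinates realising
  each class definition (orientation, span band, chromosome identity, hit
  multiplicity via a triplicated 2 kb cassette), with the forward/reverse
  roles of the ends randomised; random placements avoid the cassette so
  labels cannot be corrupted by accidental multi-hits.

Not emulated: polyploidy and homeolog structure, gapped/indel read
errors, realistic trace-quality profiles, partial-digest (restriction
site) chemistry, well-to-well cross-contamination, and de novo repeat
evolution. Passing recovery tests therefore demonstrates correctness of
the analysis logic under the stated model, not robustness to every
artefact of real trace data.

## Problem sizes used by tests and the acceptance script

The table derivations run on the packaged fixture rows and are exact.
The simulation experiments use scaled-down genomes chosen so each
completes in seconds while keeping the estimates well-conditioned:
oracle agreement uses 500 reads on a 5 Mb genome; class recovery a
42-clone planted library on three 1.5 Mb chromosomes; expansion recovery
two 3 Mb chromosomes with 80 clones (≥ 30 concordant); the full-library
run keeps the default 192 clones on ten 3 Mb chromosomes. Expansion
recovery is stochastic: with ~75 concordant clones the total-ratio
estimate scatters a few percentage points around the planted 30 %.

## Known limitations

* The mapper is ungapped and unsuitable for real trace reads with indels;
  external BLAST-style tabular alignments can be imported instead.
* E-values use fixed Karlin–Altschul parameters rather than
  composition-adjusted ones; they are a filtering device, not a
  significance claim.
* Repeat-fraction exclusion uses a hard 0.5 threshold; borderline mosaic
  reads flip categories under small threshold changes.
* Insert sizes in simulation are exact, whereas gel-estimated sizes carry
  measurement error that would widen the expansion estimate's spread.
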