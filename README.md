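# bespipe

Paired BAC-end-sequence (BES) comparative mapping, built for the kind of
library characterisation done for the SS_SBa sugarcane (variety SP80-3280)
BAC library against the ten sorghum chromosomes: given the forward and
reverse end reads of each BAC clone, a reference genome, and the clone
insert sizes, the pipeline trims and screens the reads, places each end on
the reference, classifies every clone pair into a microsynteny class,
measures how much the reference is locally expanded or contracted relative
to the clones, and summarises repeat content in a hierarchical ledger.

It is aimed at researchers working with low-coverage clone-based surveys
of large plant genomes, where a close relative's assembly (here,
sorghum for sugarcane) serves as the comparative scaffold.

## The classification at the core

Each clone yields two end reads. After E-value filtering (default
`E ≤ 1e-20`) and repeat exclusion, the best same-chromosome placement of
the pair — the one maximising the score sum of the two ends — is classified
by relative orientation and by the *outer span*
`max(ref_end) − min(ref_start)`:

| class | chromosome | orientation | span (kb) | verdict |
|-------|-----------|--------------------|-----------|------------|
| C1 | same | opposite-in (`> <`) | 20–300 | concordant |
| C2 | same | same (`>>`/`<<`) | 20–300 | discordant |
| C3 | same | opposite-in | > 300 | discordant |
| C4 | same | same | > 300 | discordant |
| C5 | same | opposite-out (`< >`)| > 300 | discordant |
| C6 | different | — | — | discordant |
| C7 | one end aligned, single hit | | | discordant |
| C8 | one end aligned, multiple hits | | | discordant |
| C9 | no end aligned | | | — |

Combinations the grid leaves open (spans < 20 kb; opposite-out ≤ 300 kb)
get extension labels X1–X4 and are reported separately.

For every concordant (C1) clone the insert size `s_q` is compared with the
placement span `s_r`; the net reference expansion over all concordant
clones is `100 · (Σs_r − Σs_q) / Σs_q`. Library fold coverage is
`n_clones · mean_insert / genome_size`, and repeat annotations roll up a
taxonomy (LTR retrotransposons → Copia/Gypsy, non-LTR, DNA transposons,
integrated viruses, simple repeats) into per-node counts, base totals and
percentages.

A synthetic-data generator produces the whole study design with planted
truth: a query genome, a reference related to it by block-wise scaling
(mean expansion 1.3×), inversions and translocations; clones with
truncated-normal insert sizes (mean 125 kb, range 29–293 kb); ~944 bp end
reads with 3′-decaying quality; organelle contamination (0.5 % of clones);
and an LTR-dominated repeat landscape (~45 % of bases).

## Worked example

Simulate a small two-chromosome dataset with a planted 1.3× mean expansion
and analyse it:

```sh
cat > demo.yaml <<EOF
seed: 42
n_chromosomes: 2
chromosome_length: 3000000
n_clones: 60
repeat_density: 0.0
contamination_rate: 0.0
EOF
bespipe simulate --config demo.yaml --out demo_ds
bespipe analyze --reads demo_ds/reads.fastq --reference demo_ds/reference.fasta \
                --inserts demo_ds/inserts.tsv --config demo.yaml --out demo_out
cat demo_out/summary.tsv
```

```
statistic	value
n_input_reads	120
n_passing_reads	120
mean_length_passing	929.4
min_length_passing	540
n_contaminated_clones	0
contamination_percent	0.0
concordant_clones	60
expansion_percent	31.26
expansion_percent_rounded	31
coverage_at_760mb	6.02
coverage_at_930mb	4.92
coverage_at_580mb	7.89
```

All 60 clones come back concordant (repeats and contamination were off and
the reads are nearly error-free), and the recovered net expansion of
31.26 % sits close to the planted 30 %. The coverage lines scale the full
36,864-clone library by the mean insert of this sample against three
candidate monoploid genome sizes.

The `tables` command re-derives the published summary statistics from the
packaged table transcriptions (`bespipe tables --out tabdir`), e.g. the
265 aligned end sequences, the 1,496,543 bp net expansion of the sorghum
syntenic regions (29.97 % ≈ the 29 % headline), and the repeat-family
fractions (Copia 48.1 % of LTR bases, LTR 85.2 % of transposable-element
bases).

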