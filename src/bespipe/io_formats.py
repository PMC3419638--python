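"""Readers and writers for the external formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  The only place
1-based inclusive coordinates appear is at the boundary with the BLAST
tabular ("outfmt 6") dialect, where the reverse strand is encoded by an
inverted subject interval; both quirks are normalised on input and
re-created on output.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("bespipe")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SeqRecord:
    """A named DNA sequence with an optional per-base quality channel.

    Quality scores are phred-like integers in [0, 60]; FASTA input has no
    quality channel and downstream code that needs one assumes a uniform
    quality of 40 (trace-quality reads in this library are high quality
    after trimming, so the implicit value is deliberately generous).
    """

    id: str
    sequence: str
    description: str = ""
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def effective_quality(self, default: int = 40) -> list[int]:
        if self.quality is not None:
            return self.quality
        return [default] * len(self.sequence)


@dataclass
class AlignmentHit:
    """One placement of a query read on a reference chromosome.

    ``ref_start < ref_end`` always; the strand carries orientation.
    """

    query_id: str
    query_start: int
    query_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    score: float
    evalue: float = 0.0
    pct_identity: float = 100.0
    mismatches: int = 0

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise FormatError(
                f"hit for {self.query_id}: ref_start {self.ref_start} "
                f">= ref_end {self.ref_end}"
            )
        if self.query_start >= self.query_end:
            raise FormatError(
                f"hit for {self.query_id}: empty query interval"
            )
        if self.strand not in "+-":
            raise FormatError(f"hit for {self.query_id}: bad strand {self.strand!r}")

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class RepeatAnnotationRecord:
    """A masked interval on a read, labelled with its repeat family.

    ``lineage`` is the ordered category path from the taxonomy root down to
    (and including) ``family``, e.g. ``("Transposable Element",
    "RNA transposon", "LTR Retrotransposon", "Copia")``.
    """

    read_id: str
    start: int
    end: int
    family: str
    lineage: tuple[str, ...] = ()
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"repeat annotation on {self.read_id}: start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file; sequences are uppercased, order preserved."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id} has empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a FASTQ file (phred+33 qualities)."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            SeqRecord(
                rec.id,
                str(rec.seq).upper(),
                rec.description[len(rec.id):].strip() if rec.description else "",
                list(rec.letter_annotations["phred_quality"]),
            )
        )
    return records


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    out = []
    for rec in records:
        bio = _BioSeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        bio.letter_annotations["phred_quality"] = rec.effective_quality()
        out.append(bio)
    SeqIO.write(out, str(path), "fastq")


# ---------------------------------------------------------------------------
# Alignment tables
# ---------------------------------------------------------------------------

_OUTFMT6_NCOLS = 12
_NATIVE_HEADER = [
    "query_id", "query_start", "query_end", "chrom", "ref_start", "ref_end",
    "strand", "score", "evalue", "pct_identity", "mismatches",
]


def read_alignment_table(path: str | Path, dialect: str = "outfmt6") -> list[AlignmentHit]:
    """Read tabular alignments.

    ``outfmt6`` is the 12-column BLAST tabular dialect: 1-based inclusive
    coordinates, reverse strand encoded as sstart > send.  ``native`` is
    this package's own TSV with explicit 0-based half-open coordinates and
    a strand column.
    """
    if dialect not in ("outfmt6", "native"):
        raise ValueError(f"unknown alignment dialect {dialect!r}")
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "native" and fields == _NATIVE_HEADER:
                continue
            try:
                if dialect == "outfmt6":
                    hits.append(_parse_outfmt6_row(fields, lineno))
                else:
                    hits.append(_parse_native_row(fields, lineno))
            except (ValueError, IndexError) as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def _parse_outfmt6_row(fields: Sequence[str], lineno: int) -> AlignmentHit:
    if len(fields) < _OUTFMT6_NCOLS:
        raise FormatError(f"line {lineno}: expected {_OUTFMT6_NCOLS} columns, got {len(fields)}")
    (qseqid, sseqid, pident, _length, mismatch, _gapopen,
     qstart, qend, sstart, send, evalue, bitscore) = fields[:_OUTFMT6_NCOLS]
    qstart, qend, sstart, send = int(qstart), int(qend), int(sstart), int(send)
    if sstart == send:
        raise FormatError(f"line {lineno}: sstart == send ({sstart})")
    if sstart < send:
        strand, ref_start, ref_end = "+", sstart - 1, send
    else:
        strand, ref_start, ref_end = "-", send - 1, sstart
    return AlignmentHit(
        query_id=qseqid,
        query_start=qstart - 1,
        query_end=qend,
        chrom=sseqid,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        score=float(bitscore),
        evalue=float(evalue),
        pct_identity=float(pident),
        mismatches=int(mismatch),
    )


def _parse_native_row(fields: Sequence[str], lineno: int) -> AlignmentHit:
    if len(fields) != len(_NATIVE_HEADER):
        raise FormatError(
            f"line {lineno}: expected {len(_NATIVE_HEADER)} columns, got {len(fields)}"
        )
    return AlignmentHit(
        query_id=fields[0],
        query_start=int(fields[1]),
        query_end=int(fields[2]),
        chrom=fields[3],
        ref_start=int(fields[4]),
        ref_end=int(fields[5]),
        strand=fields[6],
        score=float(fields[7]),
        evalue=float(fields[8]),
        pct_identity=float(fields[9]),
        mismatches=int(fields[10]),
    )


def write_alignment_table(hits: Iterable[AlignmentHit], path: str | Path,
                          dialect: str = "native") -> None:
    with open(path, "w") as fh:
        if dialect == "native":
            fh.write("\t".join(_NATIVE_HEADER) + "\n")
            for h in hits:
                fh.write("\t".join(str(x) for x in (
                    h.query_id, h.query_start, h.query_end, h.chrom,
                    h.ref_start, h.ref_end, h.strand,
                    repr(h.score), repr(h.evalue), repr(h.pct_identity),
                    h.mismatches,
                )) + "\n")
        elif dialect == "outfmt6":
            for h in hits:
                if h.strand == "+":
                    sstart, send = h.ref_start + 1, h.ref_end
                else:
                    sstart, send = h.ref_end, h.ref_start + 1
                length = h.query_end - h.query_start
                fh.write("\t".join(str(x) for x in (
                    h.query_id, h.chrom, h.pct_identity, length, h.mismatches,
                    0, h.query_start + 1, h.query_end, sstart, send,
                    h.evalue, h.score,
                )) + "\n")
        else:
            raise ValueError(f"unknown alignment dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Repeat annotation TSV (BED-like)
# ---------------------------------------------------------------------------

def read_repeat_annotations(path: str | Path) -> list[RepeatAnnotationRecord]:
    """Read read_id / start / end / family (+ optional lineage, score) rows."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            lineage: tuple[str, ...] = ()
            score = 0.0
            if len(fields) >= 5 and fields[4]:
                lineage = tuple(fields[4].split("|"))
            if len(fields) >= 6:
                score = float(fields[5])
            out.append(RepeatAnnotationRecord(
                fields[0], int(fields[1]), int(fields[2]), fields[3],
                lineage, score,
            ))
    return out


def write_repeat_annotations(annotations: Iterable[RepeatAnnotationRecord],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tstart\tend\tfamily\tlineage\tscore\n")
        for a in annotations:
            fh.write(f"{a.read_id}\t{a.start}\t{a.end}\t{a.family}\t"
                     f"{'|'.join(a.lineage)}\t{a.score:g}\n")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class Config:
    """All pipeline thresholds and simulation parameters with their defaults.

    Analysis thresholds default to the values used throughout the study this
    pipeline reproduces: BlastN-style E-value cutoff 1e-20, a concordant
    paired-end span window of 20-300 kb, an 80% query-coverage rule for
    organelle contamination, and exclusion of reads that are more than half
    repeat-masked.
    """

    # analysis thresholds
    evalue_max: float = 1e-20
    min_span: int = 20_000
    max_span: int = 300_000
    organelle_min_coverage: float = 0.80
    repeat_exclusion_fraction: float = 0.5
    allow_cross_chrom_override: bool = False  # if True, a higher-scoring cross-chromosome pair beats a same-chromosome one

    # mapper
    kmer_size: int = 15
    match_score: int = 1
    mismatch_penalty: int = 3
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46
    locus_window: int = 10_000
    repeat_min_score: float = 60.0

    # QC / trimming
    trim_window: int = 20
    trim_min_mean_q: float = 20.0
    trim_min_length: int = 100
    vector_min_seed: int = 12
    vector_max_mismatch: int = 0

    # simulation: genome
    n_chromosomes: int = 10
    chromosome_length: int = 3_000_000
    gc_content: float = 0.44
    repeat_density: float = 0.45
    repeat_divergence_min: float = 0.02
    repeat_divergence_max: float = 0.15

    # simulation: rearrangement plan
    mean_expansion: float = 1.30
    expansion_sd: float = 0.15
    block_length: int = 400_000
    inversion_rate: float = 0.05
    translocation_rate: float = 0.05

    # simulation: clones and reads
    n_clones: int = 192
    insert_mean: float = 125_000.0
    insert_sd: float = 35_000.0
    insert_min: int = 29_000
    insert_max: int = 293_000
    read_length_mean: float = 944.0
    read_length_sd: float = 150.0
    read_length_min: int = 312
    base_error_rate: float = 0.005
    contamination_rate: float = 0.005
    organelle_length: int = 150_000

    # coverage reporting: monoploid genome sizes (bp) to report fold coverage at
    genome_sizes: tuple[int, ...] = (760_000_000, 930_000_000, 580_000_000)
    library_n_clones: int = 36_864

    # randomness (mandatory for simulation commands)
    seed: int | None = None

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError("config is missing 'seed', required for simulation runs")
        return self.seed

    def replace(self, **kwargs) -> "Config":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(Config)}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Load a YAML config; every key optional, unknown keys rejected."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a mapping")
        data.update(loaded)
    data.update(overrides)
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(_CONFIG_FIELDS)}"
        )
    if "genome_sizes" in data and isinstance(data["genome_sizes"], list):
        data["genome_sizes"] = tuple(data["genome_sizes"])
    return Config(**data)


def log_stage(stage: str, n_in: int, n_out: int) -> None:
    """Record filter accounting for one pipeline stage."""
    logger.info("stage %s: %d records in, %d out, %d removed",
                stage, n_in, n_out, n_in - n_out)
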