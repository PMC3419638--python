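"""End-to-end orchestration: simulate, analyze, and worked-example tables.

``run_analyze`` is the whole analysis in one call: QC-trim the end reads,
screen clones against organelle genomes, mask repeats against a consensus
library, place the surviving ends on the reference, classify every clone's
pair into a synteny class, compute expansion/contraction statistics over
the concordant clones, roll up the repeat ledger, and write every report
as TSV next to a run manifest with per-stage record accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .expansion import (aggregate_by_chromosome, build_regions,
                        contamination_rate, coverage_estimate,
                        total_expansion_percent)
from .io_formats import (Config, SeqRecord, log_stage, read_fasta, read_fastq,
                         write_alignment_table, write_repeat_annotations)
from .mapping import SeedIndex, annotate_repeats, map_read, repeat_fraction
from .qc import QCReport, screen_organelle, trim_quality, trim_vector
from .repeat_summary import RepeatTaxonomy, summarize
from .synteny import (CLASS_LABELS, aligned_bes_total, classify_library,
                      no_hit_bes_total)
from .synthetic import make_dataset
from .tables import derive_statistics, default_fixtures_dir


@dataclass
class RunManifest:
    seed: int | None
    config: dict
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = __version__

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.stage_counts[stage] = {"in": n_in, "out": n_out,
                                    "removed": n_in - n_out}
        log_stage(stage, n_in, n_out)

    def write(self, path: Path) -> None:
        path.write_text(yaml.safe_dump({
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stage_counts": self.stage_counts,
            "outputs": self.outputs,
        }, sort_keys=False))


def split_read_id(read_id: str) -> tuple[str, str]:
    """clone id and end ('f'/'r') from a read id of the form CLONE.f."""
    clone, _, end = read_id.rpartition(".")
    if end not in ("f", "r") or not clone:
        raise ValueError(f"read id {read_id!r} is not CLONE.f / CLONE.r")
    return clone, end


def _load_reads(path: str | Path) -> list[SeqRecord]:
    path = Path(path)
    if path.suffix.lower() in (".fastq", ".fq"):
        return read_fastq(path)
    return read_fasta(path)


def _read_inserts(path: str | Path) -> dict[str, int]:
    inserts = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("clone_id\t"):
                continue
            clone, size = line.split("\t")[:2]
            inserts[clone] = int(float(size))
    return inserts


@dataclass
class AnalysisResult:
    qc: QCReport
    calls: list
    class_counts: dict[str, int]
    contaminated_clones: list[str]
    regions: list
    expansion_percent: float | None
    repeat_ledger: object | None
    repeat_percent: float | None
    coverage: dict[int, float]
    manifest: RunManifest


def run_simulate(config: Config, outdir: str | Path):
    """Wrap the synthetic-data generator and write a manifest."""
    dataset = make_dataset(config, outdir)
    manifest = RunManifest(config.seed, config.to_dict())
    manifest.record("clones", config.n_clones, len(dataset.truth.clones))
    manifest.record("reads", 2 * config.n_clones, len(dataset.reads))
    manifest.outputs = {
        "reads": str(dataset.reads_path),
        "reference": str(dataset.reference_path),
        "organelle": str(dataset.organelle_path),
        "inserts": str(dataset.inserts_path),
        "truth": str(dataset.truth_path),
    }
    manifest.write(Path(outdir) / "manifest.yaml")
    return dataset


def run_analyze(reads_path: str | Path, reference_path: str | Path,
                inserts_path: str | Path, config: Config,
                outdir: str | Path, *,
                vector_path: str | Path | None = None,
                organelle_path: str | Path | None = None,
                repeats_path: str | Path | None = None,
                taxonomy_path: str | Path | None = None) -> AnalysisResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.seed, config.to_dict())

    reads = _load_reads(reads_path)
    inserts = _read_inserts(inserts_path)
    n_input = len(reads)

    # --- vector + quality trimming -------------------------------------
    if vector_path is not None:
        vector = read_fasta(vector_path)[0].sequence
        reads = [trim_vector(r, vector, config.vector_min_seed,
                             config.vector_max_mismatch) for r in reads]
    passing: list[SeqRecord] = []
    for r in reads:
        t = trim_quality(r, config.trim_window, config.trim_min_mean_q,
                         config.trim_min_length)
        if t is not None:
            passing.append(t)
    manifest.record("qc_trim", n_input, len(passing))
    total_bases = sum(len(r) for r in passing)

    # --- organelle screen ----------------------------------------------
    contaminated_clones: set[str] = set()
    if organelle_path is not None:
        org_genome = {r.id: r.sequence for r in read_fasta(organelle_path)}
        org_index = SeedIndex.build(org_genome, k=config.kmer_size)
        for r in passing:
            hits = map_read(r, org_index,
                            match_score=config.match_score,
                            mismatch_penalty=config.mismatch_penalty,
                            karlin_lambda=config.karlin_lambda,
                            karlin_k=config.karlin_k,
                            max_evalue=config.evalue_max,
                            locus_window=config.locus_window)
            if screen_organelle(r, hits, config.evalue_max,
                                config.organelle_min_coverage):
                contaminated_clones.add(split_read_id(r.id)[0])
    manifest.record("organelle_screen", len(passing),
                    len(passing) - sum(1 for r in passing
                                       if split_read_id(r.id)[0] in contaminated_clones))

    # --- repeat masking ------------------------------------------------
    taxonomy = (RepeatTaxonomy.from_file(taxonomy_path) if taxonomy_path
                else RepeatTaxonomy.default())
    annotations = []
    excluded_ends: set[str] = set()
    if repeats_path is not None:
        library = read_fasta(repeats_path)
        for r in passing:
            anns = annotate_repeats(r, library, taxonomy,
                                    min_score=config.repeat_min_score,
                                    match_score=config.match_score,
                                    mismatch_penalty=config.mismatch_penalty)
            annotations.extend(anns)
            if repeat_fraction(r, anns) > config.repeat_exclusion_fraction:
                excluded_ends.add(r.id)
    manifest.record("repeat_exclusion", len(passing),
                    len(passing) - len(excluded_ends))

    # --- mapping ---------------------------------------------------------
    reference = {r.id: r.sequence for r in read_fasta(reference_path)}
    index = SeedIndex.build(reference, k=config.kmer_size)
    all_hits = []
    hits_by_read: dict[str, list] = {}
    mappable = [r for r in passing if r.id not in excluded_ends
                and split_read_id(r.id)[0] not in contaminated_clones]
    for r in mappable:
        hits = map_read(r, index,
                        match_score=config.match_score,
                        mismatch_penalty=config.mismatch_penalty,
                        karlin_lambda=config.karlin_lambda,
                        karlin_k=config.karlin_k,
                        max_evalue=config.evalue_max,
                        locus_window=config.locus_window)
        hits_by_read[r.id] = hits
        all_hits.extend(hits)
    manifest.record("mapping", len(mappable),
                    sum(1 for h in hits_by_read.values() if h))

    # --- classification ---------------------------------------------------
    hits_by_clone: dict[str, dict[str, list]] = {
        clone: {"f": [], "r": []} for clone in inserts}
    for read_id, hits in hits_by_read.items():
        clone, end = split_read_id(read_id)
        hits_by_clone.setdefault(clone, {"f": [], "r": []})[end] = hits
    calls, counts = classify_library(hits_by_clone, config.min_span,
                                     config.max_span,
                                     config.allow_cross_chrom_override)
    manifest.record("classification", len(hits_by_clone), len(calls))

    # --- expansion statistics ---------------------------------------------
    regions = build_regions(calls, inserts)
    chrom_summaries, totals = aggregate_by_chromosome(regions)
    expansion_pct = (total_expansion_percent(totals)
                     if totals.sum_query_bp > 0 else None)

    # --- repeat ledger ----------------------------------------------------
    ledger = repeat_pct = None
    if repeats_path is not None and total_bases > 0:
        ledger = summarize(annotations, total_bases, taxonomy)
        repeat_pct = round(100.0 * ledger.total_repeat_bases / total_bases, 2)

    # --- summary ----------------------------------------------------------
    lengths = [len(r) for r in passing]
    qc = QCReport(n_input, len(passing),
                  sum(lengths) / len(lengths) if lengths else 0.0,
                  min(lengths) if lengths else 0,
                  len(inserts), len(contaminated_clones))
    mean_insert = sum(inserts.values()) / len(inserts) if inserts else 0.0
    coverage = {g: round(coverage_estimate(config.library_n_clones, mean_insert, g), 2)
                for g in config.genome_sizes} if mean_insert else {}

    # --- reports ----------------------------------------------------------
    write_alignment_table(all_hits, outdir / "alignments.tsv", "native")
    if annotations:
        write_repeat_annotations(annotations, outdir / "repeat_annotations.tsv")
    _write_calls(calls, outdir / "synteny_calls.tsv")
    _write_counts(counts, outdir / "class_counts.tsv")
    _write_expansion(chrom_summaries, totals, outdir / "expansion_by_chromosome.tsv")
    if ledger is not None:
        _write_ledger(ledger, outdir / "repeat_ledger.tsv")
    _write_summary(qc, counts, expansion_pct, repeat_pct, coverage,
                   outdir / "summary.tsv")
    manifest.outputs = {p.name: str(p) for p in sorted(outdir.glob("*.tsv"))}
    manifest.write(outdir / "manifest.yaml")

    return AnalysisResult(qc, calls, counts, sorted(contaminated_clones),
                          regions, expansion_pct, ledger, repeat_pct,
                          coverage, manifest)


def run_tables(fixtures_dir: str | Path | None, outdir: str | Path) -> dict:
    """Recompute the worked-example statistics from the packaged tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats = derive_statistics(fixtures_dir)
    with open(outdir / "derived_statistics.tsv", "w") as fh:
        fh.write("statistic\tvalue\n")
        for k, v in stats.items():
            fh.write(f"{k}\t{v}\n")
    manifest = RunManifest(None, {"fixtures": str(fixtures_dir or default_fixtures_dir())})
    manifest.record("derived_statistics", len(stats), len(stats))
    manifest.outputs = {"derived_statistics": str(outdir / "derived_statistics.tsv")}
    manifest.write(outdir / "manifest.yaml")
    return stats


def _write_calls(calls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("clone_id\tclass\tchrom\tspan\torientation\tscore_sum\n")
        for c in calls:
            if c.placement is not None:
                p = c.placement
                fh.write(f"{c.clone_id}\t{c.class_label}\t{p.chrom}\t{p.span}\t"
                         f"{p.orientation}\t{p.score_sum:g}\n")
            elif c.single_hit is not None:
                h = c.single_hit
                fh.write(f"{c.clone_id}\t{c.class_label}\t{h.chrom}\t\t\t{h.score:g}\n")
            else:
                fh.write(f"{c.clone_id}\t{c.class_label}\t\t\t\t\n")


def _write_counts(counts: dict[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tbac_count\n")
        for label in CLASS_LABELS:
            fh.write(f"{label}\t{counts.get(label, 0)}\n")
        fh.write(f"total_clones\t{sum(counts.values())}\n")
        fh.write(f"aligned_bes_total\t{aligned_bes_total(counts)}\n")
        fh.write(f"no_hit_bes_total\t{no_hit_bes_total(counts)}\n")


def _write_expansion(summaries, totals, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tdirection\tn_regions\tquery_bp\tref_bp\tdelta_bp\n")
        for s in summaries:
            for direction, d in (("expanded", s.expanded), ("contracted", s.contracted)):
                fh.write(f"{s.chrom}\t{direction}\t{d.n_regions}\t{d.sum_query_bp}\t"
                         f"{d.sum_ref_bp}\t{d.sum_delta_bp}\n")
        fh.write(f"total\tboth\t{totals.n_regions}\t{totals.sum_query_bp}\t"
                 f"{totals.sum_ref_bp}\t{totals.sum_delta_bp}\n")


def _write_ledger(ledger, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tn_elements\tlength_bp\tpct_of_total_bases\tpct_of_repeat_bases\n")
        for label in ledger.taxonomy.labels():
            node = ledger.nodes[label]
            pct_tot = ledger.percent_of_total_bases(label)
            pct_rep = (ledger.percent_of_repeat_bases(label)
                       if ledger.total_repeat_bases else 0.0)
            fh.write(f"{label}\t{node.n_elements}\t{node.length_bp}\t"
                     f"{pct_tot}\t{pct_rep}\n")
        fh.write(f"Total\t\t{ledger.total_repeat_bases}\t"
                 f"{round(100.0 * ledger.total_repeat_bases / ledger.total_read_bases, 2)}\t100.0\n")


def _write_summary(qc: QCReport, counts, expansion_pct, repeat_pct, coverage,
                   path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        fh.write(f"n_input_reads\t{qc.n_input_reads}\n")
        fh.write(f"n_passing_reads\t{qc.n_passing_reads}\n")
        fh.write(f"mean_length_passing\t{qc.mean_length_passing:.1f}\n")
        fh.write(f"min_length_passing\t{qc.min_length_passing}\n")
        fh.write(f"n_contaminated_clones\t{qc.n_contaminated_clones}\n")
        fh.write(f"contamination_percent\t{qc.contamination_percent}\n")
        fh.write(f"concordant_clones\t{counts.get('C1', 0)}\n")
        if expansion_pct is not None:
            fh.write(f"expansion_percent\t{expansion_pct}\n")
            fh.write(f"expansion_percent_rounded\t{round(expansion_pct)}\n")
        if repeat_pct is not None:
            fh.write(f"repeat_percent_of_bases\t{repeat_pct}\n")
        for g, cov in coverage.items():
            fh.write(f"coverage_at_{g // 1_000_000}mb\t{cov}\n")
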