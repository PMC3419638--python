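"""Derived statistics recomputed from the packaged reference tables.

The pipeline ships TSV transcriptions of the published summary tables for
the SS_SBa sugarcane BAC library (library summary, per-class clone counts,
expansion/contraction sums per sorghum chromosome, repeat-content ledger).
This module re-derives every headline number from those raw rows: the
aligned/no-hit end-sequence accounting, the genome-wide expansion
percentage, fold-coverage estimates, and the repeat-family fractions.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .expansion import (SyntenicRegion, aggregate_by_chromosome,
                        contamination_rate, coverage_estimate,
                        total_expansion_percent)
from .repeat_summary import ROOT, RepeatTaxonomy, fraction_of, ledger_from_table

FIXTURE_NAMES = ("library_summary.tsv", "class_counts.tsv",
                 "expansion_by_chromosome.tsv", "repeat_content.tsv")


def default_fixtures_dir() -> Path:
    return Path(str(resources.files("bespipe").joinpath("data")))


def _read(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing fixture {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def load_library_summary(fixtures: Path) -> dict[str, float]:
    df = _read(fixtures / "library_summary.tsv")
    return dict(zip(df["key"], df["value"].astype(float)))


def load_class_counts(fixtures: Path) -> pd.DataFrame:
    return _read(fixtures / "class_counts.tsv")


def load_expansion_regions(fixtures: Path) -> list[SyntenicRegion]:
    """Expand each (chromosome, direction) aggregate row into one pseudo
    region carrying that row's sums; aggregation over these reproduces the
    printed per-chromosome and grand totals exactly."""
    df = _read(fixtures / "expansion_by_chromosome.tsv")
    regions = []
    for _, row in df.iterrows():
        if int(row["n_regions"]) == 0:
            continue
        n = int(row["n_regions"])
        # split a row of n regions into n pseudo-regions preserving both the
        # sums and the direction of every region in the bundle: n-1 minimal
        # regions of the right direction, the remainder on the first
        q, r = int(row["sugarcane_bp"]), int(row["sorghum_bp"])
        if row["direction"] == "expanded":
            small_q, small_r = 1, 2
        else:
            small_q, small_r = 2, 1
        first_q = q - small_q * (n - 1)
        first_r = r - small_r * (n - 1)
        if (first_r > first_q) != (row["direction"] == "expanded"):
            raise ValueError(f"row {row['chrom']}/{row['direction']}: sums "
                             "contradict the stated direction")
        splits = [(first_q, first_r)] + [(small_q, small_r)] * (n - 1)
        for i, (qq, rr) in enumerate(splits):
            regions.append(SyntenicRegion(f"{row['chrom']}.{row['direction']}.{i}",
                                          row["chrom"], qq, rr))
    return regions


def load_repeat_ledger(fixtures: Path, taxonomy: RepeatTaxonomy | None = None):
    df = _read(fixtures / "repeat_content.tsv")
    taxonomy = taxonomy or RepeatTaxonomy.default()
    rows = [(r["label"], int(r["n_elements"]), int(r["length_bp"]))
            for _, r in df.iterrows()]
    total_row = df[df["label"] == "Total"].iloc[0]
    # the ledger reports masked bases as a fraction of all read bases; the
    # read-base total is implied by the printed percentage
    total_read_bases = round(100.0 * total_row["length_bp"] / total_row["pct_of_total_bases"])
    return ledger_from_table(rows, int(total_read_bases), taxonomy)


def derive_statistics(fixtures: str | Path | None = None) -> dict[str, float]:
    """Recompute every headline quantity from the raw fixture rows."""
    fixtures = Path(fixtures) if fixtures is not None else default_fixtures_dir()
    lib = load_library_summary(fixtures)
    classes = load_class_counts(fixtures)
    regions = load_expansion_regions(fixtures)
    ledger = load_repeat_ledger(fixtures)

    counts = dict(zip(classes["class"], classes["bac_count"].astype(int)))
    aligned = dict(zip(classes["class"], classes["aligned_bes"].astype(int)))
    aligned_bes = sum(aligned[c] * counts[c] for c in counts)
    n_bes = int(lib["n_high_quality_bes"])
    discordant_same_chrom = sum(counts[c] for c in ("C2", "C3", "C4", "C5"))

    _, totals = aggregate_by_chromosome(regions)
    expansion_pct = total_expansion_percent(totals)

    mean_insert_bp = lib["mean_insert_kb"] * 1000
    n_lib = int(lib["n_clones"])

    out = {
        "clone_total": sum(counts.values()),
        "aligned_bes_total": aligned_bes,
        "no_hit_bes_total": n_bes - aligned_bes,
        "discordant_same_chrom_bacs": discordant_same_chrom,
        "concordant_bacs": counts["C1"],
        "sugarcane_bp_total": totals.sum_query_bp,
        "sorghum_bp_total": totals.sum_ref_bp,
        "expansion_delta_bp": totals.sum_delta_bp,
        "expanded_region_count": totals.n_expanded,
        "contracted_region_count": totals.n_contracted,
        "expansion_percent": expansion_pct,
        "expansion_percent_rounded": round(expansion_pct),
        "copia_pct_of_ltr": fraction_of(ledger, "Copia", "LTR Retrotransposon"),
        "gypsy_pct_of_ltr": fraction_of(ledger, "Gypsy", "LTR Retrotransposon"),
        "ltr_pct_of_transposable": fraction_of(ledger, "LTR Retrotransposon",
                                               "Transposable Element"),
        "nonltr_pct_of_repeats": fraction_of(ledger, "Non-LTR Retrotransposon", ROOT),
        "dna_transposon_pct_of_repeats": fraction_of(ledger, "DNA transposon", ROOT),
        "transposable_pct_of_repeats": fraction_of(ledger, "Transposable Element", ROOT),
        "repeat_pct_of_read_bases": round(
            100.0 * ledger.total_repeat_bases / ledger.total_read_bases, 2),
        "coverage_at_760mb": round(coverage_estimate(
            n_lib, mean_insert_bp, lib["monoploid_genome_size_min_mb"] * 1e6), 2),
        "coverage_at_930mb": round(coverage_estimate(
            n_lib, mean_insert_bp, lib["monoploid_genome_size_max_mb"] * 1e6), 2),
        "coverage_at_580mb": round(coverage_estimate(
            n_lib, mean_insert_bp, lib["revised_monoploid_genome_size_mb"] * 1e6), 2),
        "contamination_percent": contamination_rate(
            int(lib["chloroplast_contaminated_clones"]), int(lib["n_sampled_clones"])),
    }
    return out
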