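"""Expansion/contraction statistics for concordant clones.

For every concordant (C1) clone, the reference span of its paired-end
placement is compared with the clone's insert size.  A reference span
larger than the insert means the reference genome is locally expanded
relative to the query genome the clone came from; smaller means
contracted.  Per-chromosome sums and a genome-wide expansion percentage
follow directly, as do fold-coverage estimates for the whole library and
the contamination rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .synteny import SyntenyCall

EXPANDED = "expanded"
CONTRACTED = "contracted"


@dataclass
class SyntenicRegion:
    """One concordant clone: insert size vs. projected reference span."""

    clone_id: str
    chrom: str
    query_bp: int       # clone insert size (query genome, e.g. sugarcane)
    ref_bp: int         # outer span of the placement (reference, e.g. sorghum)

    @property
    def delta_bp(self) -> int:
        return self.ref_bp - self.query_bp

    @property
    def direction(self) -> str:
        # a tie (delta 0) counts as contracted: "expanded" strictly means larger
        return EXPANDED if self.delta_bp > 0 else CONTRACTED


@dataclass
class DirectionSummary:
    n_regions: int = 0
    sum_query_bp: int = 0
    sum_ref_bp: int = 0

    @property
    def sum_delta_bp(self) -> int:
        return self.sum_ref_bp - self.sum_query_bp

    def add(self, region: SyntenicRegion) -> None:
        self.n_regions += 1
        self.sum_query_bp += region.query_bp
        self.sum_ref_bp += region.ref_bp


@dataclass
class ChromosomeSummary:
    chrom: str
    expanded: DirectionSummary
    contracted: DirectionSummary


@dataclass
class GrandTotals:
    n_regions: int
    n_expanded: int
    n_contracted: int
    sum_query_bp: int
    sum_ref_bp: int

    @property
    def sum_delta_bp(self) -> int:
        return self.sum_ref_bp - self.sum_query_bp


def build_regions(calls: list[SyntenyCall],
                  insert_sizes: dict[str, int]) -> list[SyntenicRegion]:
    """One region per concordant call; every other class is ignored."""
    regions = []
    for call in calls:
        if call.class_label != "C1":
            continue
        if call.clone_id not in insert_sizes:
            raise KeyError(f"no insert size for concordant clone {call.clone_id}")
        p = call.placement
        regions.append(SyntenicRegion(call.clone_id, p.chrom,
                                      int(insert_sizes[call.clone_id]),
                                      int(p.span)))
    return regions


def aggregate_by_chromosome(regions: list[SyntenicRegion]
                            ) -> tuple[list[ChromosomeSummary], GrandTotals]:
    by_chrom: dict[str, ChromosomeSummary] = {}
    n_exp = n_con = sum_q = sum_r = 0
    for region in regions:
        summ = by_chrom.get(region.chrom)
        if summ is None:
            summ = ChromosomeSummary(region.chrom, DirectionSummary(),
                                     DirectionSummary())
            by_chrom[region.chrom] = summ
        if region.direction == EXPANDED:
            summ.expanded.add(region)
            n_exp += 1
        else:
            summ.contracted.add(region)
            n_con += 1
        sum_q += region.query_bp
        sum_r += region.ref_bp
    summaries = [by_chrom[c] for c in sorted(by_chrom)]
    return summaries, GrandTotals(len(regions), n_exp, n_con, sum_q, sum_r)


def total_expansion_percent(totals: GrandTotals) -> float:
    """Net reference expansion over all concordant regions, in percent:
    100 * (sum_ref - sum_query) / sum_query, to two decimals."""
    if totals.sum_query_bp <= 0:
        raise ValueError("total query bp must be positive")
    return round(100.0 * totals.sum_delta_bp / totals.sum_query_bp, 2)


def coverage_estimate(n_clones: int, mean_insert_bp: float,
                      genome_size_bp: float) -> float:
    """Fold coverage of a monoploid genome by the whole clone library."""
    if n_clones <= 0 or mean_insert_bp <= 0 or genome_size_bp <= 0:
        raise ValueError("all coverage inputs must be positive")
    return n_clones * mean_insert_bp / genome_size_bp


def contamination_rate(n_contaminated: int, n_clones: int) -> float:
    """Contaminated clones as a percentage, one decimal."""
    if n_clones <= 0:
        raise ValueError("n_clones must be positive")
    if not 0 <= n_contaminated <= n_clones:
        raise ValueError("n_contaminated out of range")
    return round(100.0 * n_contaminated / n_clones, 1)
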