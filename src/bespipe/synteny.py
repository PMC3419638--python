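"""Paired-end microsynteny classification of BAC clones.

Each clone contributes a forward and a reverse end sequence.  The pair's
best same-chromosome placement (maximum score sum over all forward/reverse
hit combinations) is classified by the relative orientation of the two hits
and by the outer span between them:

=====  ==========  =============  ============  ===========
class  chromosome  orientation    span (kb)     verdict
=====  ==========  =============  ============  ===========
C1     same        opposite-in    20 - 300      concordant
C2     same        same           20 - 300      discordant
C3     same        opposite-in    > 300         discordant
C4     same        same           > 300         discordant
C5     same        opposite-out   > 300         discordant
C6     different   --             --            discordant
C7     one end aligned, single hit               discordant
C8     one end aligned, multiple hits            discordant
C9     no end aligned                            --
=====  ==========  =============  ============  ===========

Combinations the grid above leaves uncovered (spans below 20 kb, and
opposite-out spans up to 300 kb) receive extension labels X1-X4 and are
reported distinctly; they are never folded into C1-C6.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AlignmentHit

CLASS_LABELS = ["C1", "C2", "C3", "C4", "C5", "C6", "C7", "C8", "C9",
                "X1", "X2", "X3", "X4"]

OPPOSITE_IN = "opposite_in"
OPPOSITE_OUT = "opposite_out"
SAME = "same"


@dataclass
class PairPlacement:
    clone_id: str
    hit_f: AlignmentHit
    hit_r: AlignmentHit
    score_sum: float
    span: int
    orientation: str

    @property
    def chrom(self) -> str:
        return self.hit_f.chrom


@dataclass
class SyntenyCall:
    clone_id: str
    class_label: str
    placement: PairPlacement | None = None
    single_hit: AlignmentHit | None = None

    @property
    def concordant(self) -> bool:
        return self.class_label == "C1"


def pair_orientation(hit_a: AlignmentHit, hit_b: AlignmentHit) -> str:
    """Relative orientation of two same-chromosome hits.

    With U the upstream hit (smaller ref_start) and D the other:
    opposite-in is ``U:+ D:-`` (ends pointing at each other, ``> <``),
    opposite-out ``U:- D:+`` (``< >``), and same when strands agree.
    """
    if hit_a.chrom != hit_b.chrom:
        raise ValueError("pair_orientation requires same-chromosome hits")
    u, d = (hit_a, hit_b) if hit_a.ref_start <= hit_b.ref_start else (hit_b, hit_a)
    if u.strand == d.strand:
        return SAME
    return OPPOSITE_IN if u.strand == "+" else OPPOSITE_OUT


def outer_span(hit_a: AlignmentHit, hit_b: AlignmentHit) -> int:
    return max(hit_a.ref_end, hit_b.ref_end) - min(hit_a.ref_start, hit_b.ref_start)


def _paired_class(orientation: str, span: int, min_span: int, max_span: int) -> str:
    in_range = min_span <= span <= max_span
    long = span > max_span
    if orientation == OPPOSITE_IN:
        return "C1" if in_range else ("C3" if long else "X1")
    if orientation == SAME:
        return "C2" if in_range else ("C4" if long else "X2")
    # opposite-out
    return "C5" if long else ("X4" if in_range else "X3")


def select_best_placement(clone_id: str, hits_f: list[AlignmentHit],
                          hits_r: list[AlignmentHit], min_span: int = 20_000,
                          max_span: int = 300_000) -> PairPlacement | None:
    """Best same-chromosome pairing by score sum.

    Ties are broken by preferring a concordant pairing (opposite-in within
    the span window), then the smaller span, then the lexicographically
    smaller chromosome name.
    """
    best: tuple | None = None
    chosen: PairPlacement | None = None
    for hf in hits_f:
        for hr in hits_r:
            if hf.chrom != hr.chrom:
                continue
            span = outer_span(hf, hr)
            orient = pair_orientation(hf, hr)
            concordant = orient == OPPOSITE_IN and min_span <= span <= max_span
            key = (-(hf.score + hr.score), 0 if concordant else 1, span, hf.chrom)
            if best is None or key < best:
                best = key
                chosen = PairPlacement(clone_id, hf, hr, hf.score + hr.score,
                                       span, orient)
    return chosen


def classify_pair(clone_id: str, hits_f: list[AlignmentHit],
                  hits_r: list[AlignmentHit], min_span: int = 20_000,
                  max_span: int = 300_000,
                  allow_cross_chrom_override: bool = False) -> SyntenyCall:
    """Classify one clone from the filtered hit lists of its two ends.

    A same-chromosome pairing, when one exists, always wins over any
    cross-chromosome combination (C6 is the fallback), unless
    ``allow_cross_chrom_override`` lets a strictly higher-scoring
    cross-chromosome pair take precedence.
    """
    if hits_f and hits_r:
        placement = select_best_placement(clone_id, hits_f, hits_r,
                                          min_span, max_span)
        if placement is not None and allow_cross_chrom_override:
            best_cross = max((hf.score + hr.score for hf in hits_f for hr in hits_r
                              if hf.chrom != hr.chrom), default=float("-inf"))
            if best_cross > placement.score_sum:
                placement = None
        if placement is None:
            return SyntenyCall(clone_id, "C6")
        label = _paired_class(placement.orientation, placement.span,
                              min_span, max_span)
        return SyntenyCall(clone_id, label, placement=placement)
    if hits_f or hits_r:
        hits = hits_f or hits_r
        label = "C7" if len(hits) == 1 else "C8"
        return SyntenyCall(clone_id, label, single_hit=hits[0])
    return SyntenyCall(clone_id, "C9")


def classify_library(hits_by_clone: dict[str, dict[str, list[AlignmentHit]]],
                     min_span: int = 20_000, max_span: int = 300_000,
                     allow_cross_chrom_override: bool = False
                     ) -> tuple[list[SyntenyCall], dict[str, int]]:
    """One call per clone plus the class-count table.

    ``hits_by_clone`` maps clone_id -> {"f": hits, "r": hits}; an excluded
    or rejected end is represented by an empty list.
    """
    calls = []
    for clone_id in sorted(hits_by_clone):
        ends = hits_by_clone[clone_id]
        extra = set(ends) - {"f", "r"}
        if extra:
            raise ValueError(f"clone {clone_id} has unexpected ends {sorted(extra)}")
        calls.append(classify_pair(clone_id, ends.get("f", []), ends.get("r", []),
                                   min_span, max_span, allow_cross_chrom_override))
    counts = {label: 0 for label in CLASS_LABELS}
    for c in calls:
        counts[c.class_label] += 1
    return calls, counts


def aligned_bes_total(counts: dict[str, int]) -> int:
    """Number of end sequences with at least one accepted placement:
    two per both-ends-aligned clone, one per single-end clone."""
    both = sum(counts.get(c, 0) for c in
               ("C1", "C2", "C3", "C4", "C5", "C6", "X1", "X2", "X3", "X4"))
    single = counts.get("C7", 0) + counts.get("C8", 0)
    return 2 * both + single


def no_hit_bes_total(counts: dict[str, int]) -> int:
    """Number of end sequences without any accepted placement."""
    return 2 * counts.get("C9", 0) + counts.get("C7", 0) + counts.get("C8", 0)
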