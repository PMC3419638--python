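"""Seed-and-extend read placement on a reference genome.

The mapper is deliberately simple: exact k-mer seeds gathered per
(chromosome, strand, diagonal), followed by the best-scoring ungapped
segment on each candidate diagonal (match +1, mismatch -3 by default).
Raw scores are converted to a BLAST-style expectation value with fixed
Karlin-Altschul parameters, and hits above the E-value cutoff are dropped.
This is sufficient for the substitution-only error model of the synthetic
reads; it makes no attempt at gapped or protein-space alignment.

``brute_force_map`` is an independent exhaustive oracle for small genomes,
used to validate the seeded mapper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignmentHit, RepeatAnnotationRecord, SeqRecord, revcomp

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def encode(seq: str) -> np.ndarray:
    """2-bit encode a DNA string; non-ACGT bases become -1 (never match)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers at every position; -1 where a window holds an
    invalid base."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j:j + n]
        out = out * 4 + np.where(window < 0, 0, window)
        bad |= window < 0
    out[bad] = -1
    return out


@dataclass
class SeedIndex:
    """Sorted-array k-mer index over a multi-chromosome reference.

    Chromosomes are concatenated; k-mers spanning a boundary are masked out.
    Lookup is O(log n) by binary search on the sorted k-mer codes.
    """

    k: int
    chrom_names: list[str]
    chrom_offsets: np.ndarray          # concatenated start offset per chrom
    chrom_lengths: np.ndarray
    genome_codes: np.ndarray           # 2-bit codes of the concatenation
    _sorted_kmers: np.ndarray = field(repr=False, default=None)
    _sorted_positions: np.ndarray = field(repr=False, default=None)

    @classmethod
    def build(cls, genome: dict[str, str] | list[SeqRecord], k: int = 15) -> "SeedIndex":
        if k < 11:
            raise ValueError("k must be >= 11")
        if isinstance(genome, dict):
            items = list(genome.items())
        else:
            items = [(r.id, r.sequence) for r in genome]
        names = [name for name, _ in items]
        lengths = np.array([len(seq) for _, seq in items], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(lengths)[:-1]]) if items else np.zeros(0, np.int64)
        concat = "".join(seq for _, seq in items)
        codes = encode(concat)
        kmers = _kmer_codes(codes, k)
        # mask k-mers that straddle a chromosome boundary
        for off, length in zip(offsets, lengths):
            lo = max(off + length - k + 1, 0)
            hi = min(off + length, len(kmers))
            if lo < hi:
                kmers[lo:hi] = -1
        valid = np.nonzero(kmers >= 0)[0]
        order = np.argsort(kmers[valid], kind="stable")
        idx = cls(k, names, offsets, lengths, codes)
        idx._sorted_kmers = kmers[valid][order]
        idx._sorted_positions = valid[order]
        return idx

    @property
    def total_length(self) -> int:
        return int(self.chrom_lengths.sum())

    def lookup(self, kmer_code: int) -> np.ndarray:
        """Concatenated-genome positions where this k-mer occurs."""
        lo = np.searchsorted(self._sorted_kmers, kmer_code, "left")
        hi = np.searchsorted(self._sorted_kmers, kmer_code, "right")
        return self._sorted_positions[lo:hi]

    def seed_diagonals(self, query_kmers: np.ndarray) -> set[int]:
        """Distinct (genome position - query position) diagonals over every
        seed match of the query's k-mer array (vectorised lookup)."""
        valid = np.nonzero(query_kmers >= 0)[0]
        if len(valid) == 0:
            return set()
        codes = query_kmers[valid]
        lo = np.searchsorted(self._sorted_kmers, codes, "left")
        hi = np.searchsorted(self._sorted_kmers, codes, "right")
        diagonals: set[int] = set()
        for q, l, h in zip(valid, lo, hi):
            if h > l:
                diagonals.update((self._sorted_positions[l:h] - q).tolist())
        return diagonals

    def chrom_of(self, pos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.chrom_offsets, pos, "right")) - 1
        return self.chrom_names[ci], int(pos - self.chrom_offsets[ci])

    def chrom_bounds(self, pos: int) -> tuple[int, int]:
        ci = int(np.searchsorted(self.chrom_offsets, pos, "right")) - 1
        start = int(self.chrom_offsets[ci])
        return start, start + int(self.chrom_lengths[ci])


def _best_ungapped_segment(match: np.ndarray, match_score: int,
                           mismatch_penalty: int) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment of a +match/-mismatch profile.

    Returns (start, end, score) with end exclusive; (0, 0, 0) when every
    segment scores <= 0.
    """
    vals = np.where(match, match_score, -mismatch_penalty).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(vals)])
    run_min = np.minimum.accumulate(cs[:-1])
    gains = cs[1:] - run_min
    end = int(np.argmax(gains)) + 1
    score = int(gains[end - 1])
    if score <= 0:
        return 0, 0, 0
    # leftmost prefix-minimum before `end` achieving the gain
    start = int(np.searchsorted(cs[:end], cs[end] - score, "left"))
    return start, end, score


def evalue_of(score: float, read_len: int, db_len: int,
              lam: float = 1.28, k_param: float = 0.46) -> float:
    """Karlin-Altschul expectation for an ungapped score."""
    log_e = math.log(k_param) + math.log(read_len) + math.log(db_len) - lam * score
    if log_e > 700:
        return math.inf
    return math.exp(log_e)


def map_read(read: SeqRecord, index: SeedIndex, *,
             match_score: int = 1, mismatch_penalty: int = 3,
             karlin_lambda: float = 1.28, karlin_k: float = 0.46,
             max_evalue: float = 1e-20,
             locus_window: int = 10_000) -> list[AlignmentHit]:
    """Place one read on the indexed reference.

    Both strands are searched by mapping the read and its reverse
    complement; only the best hit per (chromosome, strand, ``locus_window``)
    is kept, emulating one-HSP-per-locus reporting.  Hits are sorted by
    score descending.
    """
    if len(read) < index.k:
        return []
    hits: list[AlignmentHit] = []
    n_db = index.total_length
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        read_codes = encode(seq)
        kmers = _kmer_codes(read_codes, index.k)
        diagonals = index.seed_diagonals(kmers)
        L = len(seq)
        for diag in sorted(diagonals):
            lo, hi = diag, diag + L
            cb_lo, cb_hi = index.chrom_bounds(min(max(diag, 0), n_db - 1))
            # clip the read window to the chromosome holding the diagonal
            q_lo = max(0, cb_lo - diag)
            q_hi = min(L, cb_hi - diag)
            if q_hi - q_lo < index.k:
                continue
            gseg = index.genome_codes[diag + q_lo:diag + q_hi]
            rseg = read_codes[q_lo:q_hi]
            match = (gseg == rseg) & (rseg >= 0)
            s, e, score = _best_ungapped_segment(match, match_score, mismatch_penalty)
            if score <= 0:
                continue
            ev = evalue_of(score, len(read), n_db, karlin_lambda, karlin_k)
            if ev > max_evalue:
                continue
            seg_match = match[s:e]
            n_mm = int((~seg_match).sum())
            g_start = diag + q_lo + s
            chrom, roff = index.chrom_of(g_start)
            seg_len = e - s
            if strand == "+":
                q_start, q_end = q_lo + s, q_lo + e
            else:
                q_start, q_end = L - (q_lo + e), L - (q_lo + s)
            hits.append(AlignmentHit(
                query_id=read.id, query_start=q_start, query_end=q_end,
                chrom=chrom, ref_start=roff, ref_end=roff + seg_len,
                strand=strand, score=float(score), evalue=ev,
                pct_identity=100.0 * (seg_len - n_mm) / seg_len,
                mismatches=n_mm,
            ))
    return _best_per_locus(hits, locus_window)


def _best_per_locus(hits: list[AlignmentHit], window: int) -> list[AlignmentHit]:
    """Keep only the best hit per (chrom, strand, window) bucket."""
    best: dict[tuple[str, str, int], AlignmentHit] = {}
    for h in hits:
        key = (h.chrom, h.strand, h.ref_start // window)
        prev = best.get(key)
        if prev is None or h.score > prev.score:
            best[key] = h
    out = list(best.values())
    out.sort(key=lambda h: (-h.score, h.chrom, h.ref_start, h.strand))
    return out


def brute_force_map(read: SeqRecord, genome: dict[str, str],
                    max_mismatch: int = 0,
                    match_score: int = 1,
                    mismatch_penalty: int = 3) -> list[AlignmentHit]:
    """Exhaustive full-read window scan of both strands; test oracle.

    Reports every placement of the whole read with at most ``max_mismatch``
    substitutions.  Intended for genomes of a few megabases; the exact
    (``max_mismatch == 0``) path uses plain substring search, the inexact
    path a naive scan suitable only for very small genomes.
    """
    L = len(read)
    hits: list[AlignmentHit] = []
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        for chrom, ref in genome.items():
            if L > len(ref) or L == 0:
                continue
            if max_mismatch == 0:
                pos = ref.find(seq)
                while pos != -1:
                    hits.append(AlignmentHit(
                        read.id, 0, L, chrom, pos, pos + L, strand,
                        float(L * match_score), 0.0, 100.0, 0))
                    pos = ref.find(seq, pos + 1)
            else:
                ref_codes = encode(ref)
                read_codes = encode(seq)
                for pos in range(len(ref) - L + 1):
                    mm = int((ref_codes[pos:pos + L] != read_codes).sum())
                    if mm <= max_mismatch:
                        hits.append(AlignmentHit(
                            read.id, 0, L, chrom, pos, pos + L, strand,
                            float((L - mm) * match_score - mm * mismatch_penalty),
                            0.0, 100.0 * (L - mm) / L, mm))
    hits.sort(key=lambda h: (-h.score, h.chrom, h.ref_start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Repeat annotation
# ---------------------------------------------------------------------------

def annotate_repeats(read: SeqRecord, library: list[SeqRecord],
                     taxonomy, *, k: int = 13,
                     min_score: float = 60.0,
                     match_score: int = 1,
                     mismatch_penalty: int = 3) -> list[RepeatAnnotationRecord]:
    """Mask a read against a repeat consensus library.

    Each library record's id is a leaf family of ``taxonomy``.  Matching
    intervals from the same family are merged; overlaps across families are
    resolved in favour of the higher score (ties: longer interval, then
    lexicographically smaller family), the loser being trimmed to its
    uncovered part.  The result is a set of non-overlapping intervals.
    """
    read_index = SeedIndex.build({"read": read.sequence}, k=max(k, 11))
    raw: list[RepeatAnnotationRecord] = []
    read_codes = encode(read.sequence)
    L = len(read)
    for consensus in library:
        for cseq in (consensus.sequence, revcomp(consensus.sequence)):
            ccodes = encode(cseq)
            kmers = _kmer_codes(ccodes, read_index.k)
            diagonals = read_index.seed_diagonals(kmers)
            for diag in sorted(diagonals):
                c_lo = max(0, -diag)
                c_hi = min(len(cseq), L - diag)
                if c_hi - c_lo < read_index.k:
                    continue
                rseg = read_codes[diag + c_lo:diag + c_hi]
                cseg = ccodes[c_lo:c_hi]
                match = (rseg == cseg) & (cseg >= 0)
                s, e, score = _best_ungapped_segment(match, match_score, mismatch_penalty)
                if score < min_score:
                    continue
                raw.append(RepeatAnnotationRecord(
                    read.id, diag + c_lo + s, diag + c_lo + e,
                    consensus.id, taxonomy.lineage_of(consensus.id),
                    float(score)))
    return resolve_annotations(raw)


def resolve_annotations(raw: list[RepeatAnnotationRecord]) -> list[RepeatAnnotationRecord]:
    """Merge same-family overlaps, then settle cross-family conflicts by
    score (ties: longer, then lexicographic family)."""
    by_family: dict[str, list[RepeatAnnotationRecord]] = {}
    for a in raw:
        by_family.setdefault(a.family, []).append(a)
    merged: list[RepeatAnnotationRecord] = []
    for family, anns in by_family.items():
        anns.sort(key=lambda a: a.start)
        cur = anns[0]
        cur_start, cur_end, cur_score = cur.start, cur.end, cur.score
        for a in anns[1:]:
            if a.start <= cur_end:
                cur_end = max(cur_end, a.end)
                cur_score = max(cur_score, a.score)
            else:
                merged.append(RepeatAnnotationRecord(
                    cur.read_id, cur_start, cur_end, family, cur.lineage, cur_score))
                cur_start, cur_end, cur_score = a.start, a.end, a.score
        merged.append(RepeatAnnotationRecord(
            cur.read_id, cur_start, cur_end, family, cur.lineage, cur_score))
    # greedy acceptance in priority order; later annotations are trimmed to
    # whatever the accepted set leaves uncovered (contiguous remainder only)
    merged.sort(key=lambda a: (-a.score, -(a.end - a.start), a.family, a.start))
    accepted: list[RepeatAnnotationRecord] = []
    for a in merged:
        start, end = a.start, a.end
        for b in accepted:
            if b.end <= start or b.start >= end:
                continue
            if b.start <= start and b.end >= end:
                start = end  # fully covered
                break
            if b.start <= start:
                start = b.end
            elif b.end >= end:
                end = b.start
            else:
                # accepted interval splits the candidate; keep the longer side
                left = (start, b.start)
                right = (b.end, end)
                start, end = max((left, right), key=lambda iv: iv[1] - iv[0])
        if end - start > 0:
            accepted.append(RepeatAnnotationRecord(
                a.read_id, start, end, a.family, a.lineage, a.score))
    accepted.sort(key=lambda a: a.start)
    return accepted


def repeat_fraction(read: SeqRecord,
                    annotations: list[RepeatAnnotationRecord]) -> float:
    """Fraction of the read covered by the union of its repeat intervals."""
    if not annotations:
        return 0.0
    ivs = sorted((a.start, a.end) for a in annotations)
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total / len(read)
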