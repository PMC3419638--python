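"""Vector/quality trimming and organelle-contamination screening of BES reads.

Trimming follows the EST-era recipe: strip read ends that match a vector
terminus, then keep the longest stretch in which every sliding window of
base qualities clears a mean threshold.  Contamination is called per clone
(either end similar to an organelle genome at E <= 1e-20 over >= 80% of the
read), matching how plastid carry-over is reported for BAC libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AlignmentHit, SeqRecord, revcomp


@dataclass
class QCReport:
    n_input_reads: int
    n_passing_reads: int
    mean_length_passing: float
    min_length_passing: int
    n_clones: int
    n_contaminated_clones: int

    @property
    def contamination_percent(self) -> float:
        if self.n_clones == 0:
            raise ValueError("no clones")
        return round(100.0 * self.n_contaminated_clones / self.n_clones, 1)

    @property
    def n_rejected_reads(self) -> int:
        return self.n_input_reads - self.n_passing_reads


# ---------------------------------------------------------------------------
# Vector trimming
# ---------------------------------------------------------------------------

def _match_run(a: str, b: str, max_mismatch: int) -> int:
    """Length of the longest prefix over which a and b differ in at most
    ``max_mismatch`` positions."""
    mm = 0
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            mm += 1
            if mm > max_mismatch:
                return i
    return n


def trim_vector(read: SeqRecord, vector: str, min_seed: int = 12,
                max_mismatch: int = 0) -> SeqRecord:
    """Remove vector sequence from the ends of a read.

    The longest read prefix (and suffix) that continues a vector substring
    for at least ``min_seed`` bases with at most ``max_mismatch``
    mismatches is removed.  A vector match strictly interior to the read
    removes the shorter flank along with it (the longer flank is kept as
    the insert).  Reads shorter than ``min_seed`` are returned unchanged.
    """
    if min_seed < 12:
        raise ValueError("min_seed must be >= 12")
    if len(read) < min_seed or not vector:
        return read
    seq = read.sequence
    vecs = (vector.upper(), revcomp(vector.upper()))

    # longest vector-derived prefix of the read, starting anywhere in vector
    def longest_end_match(s: str) -> int:
        best = 0
        for v in vecs:
            starts = _candidate_starts(s, v, min_seed)
            for vs in starts:
                run = _match_run(s, v[vs:], max_mismatch)
                if run >= min_seed:
                    best = max(best, run)
        return best

    cut_l = longest_end_match(seq)
    rc = revcomp(seq)
    cut_r = longest_end_match(rc)
    if cut_l + cut_r >= len(seq):
        # read is entirely vector; keep the (possibly empty) longer remnant
        keep = seq[cut_l:] if cut_l >= cut_r else seq[:len(seq) - cut_r]
        return _slice(read, cut_l if cut_l >= cut_r else 0,
                      len(seq) if cut_l >= cut_r else len(seq) - cut_r) \
            if keep else _slice(read, 0, 0)
    trimmed = _slice(read, cut_l, len(seq) - cut_r)

    # interior hit: drop the shorter flank.  Interior detection demands a
    # longer match (2x min_seed) than end trimming: a 12 bp exact match
    # arises by chance in a ~1 kb read against a multi-kb vector, while true
    # interior vector carry-over is tens of bases.
    hit = _interior_hit(trimmed.sequence, vecs, 2 * min_seed, max_mismatch)
    if hit is not None:
        s, e = hit
        left_len, right_len = s, len(trimmed) - e
        if left_len >= right_len:
            trimmed = _slice(trimmed, 0, s)
        else:
            trimmed = _slice(trimmed, e, len(trimmed))
    return trimmed


def _candidate_starts(s: str, v: str, min_seed: int) -> set[int]:
    """Vector offsets whose substring could extend a match at the start of s."""
    seed = s[:min_seed]
    if len(seed) < min_seed:
        return set()
    starts = set()
    pos = v.find(seed)
    while pos != -1:
        starts.add(pos)
        pos = v.find(seed, pos + 1)
    return starts


def _interior_hit(seq: str, vecs: tuple[str, str], min_seed: int,
                  max_mismatch: int) -> tuple[int, int] | None:
    """Longest exact-seeded vector match inside the read, or None."""
    best: tuple[int, int] | None = None
    for v in vecs:
        for off in range(0, max(len(v) - min_seed + 1, 0)):
            seed = v[off:off + min_seed]
            pos = seq.find(seed)
            while pos != -1:
                run = _match_run(seq[pos:], v[off:], max_mismatch)
                if run >= min_seed and (best is None or run > best[1] - best[0]):
                    best = (pos, pos + run)
                pos = seq.find(seed, pos + 1)
    return best


def _slice(read: SeqRecord, start: int, end: int) -> SeqRecord:
    q = read.quality[start:end] if read.quality is not None else None
    return SeqRecord(read.id, read.sequence[start:end], read.description, q)


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------

def trim_quality(read: SeqRecord, window: int = 20, min_mean_q: float = 20.0,
                 min_length: int = 100) -> SeqRecord | None:
    """Keep the largest segment whose every length-``window`` sliding window
    has mean quality >= ``min_mean_q``; returns None (rejection) when the
    kept segment is shorter than ``min_length``."""
    if window < 1:
        raise ValueError("window must be >= 1")
    qual = np.asarray(read.effective_quality(), dtype=float)
    n = len(qual)
    if n == 0:
        return None
    if n < window:
        if qual.mean() >= min_mean_q and n >= min_length:
            return read
        return None
    cs = np.concatenate([[0.0], np.cumsum(qual)])
    means = (cs[window:] - cs[:-window]) / window
    good = means >= min_mean_q
    # longest run of consecutive good windows
    best_len, best_start, run_start = 0, 0, None
    for i, g in enumerate(good):
        if g and run_start is None:
            run_start = i
        elif not g and run_start is not None:
            if i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if run_start is not None and len(good) - run_start > best_len:
        best_len, best_start = len(good) - run_start, run_start
    if best_len == 0:
        return None
    start, end = best_start, best_start + best_len - 1 + window
    if end - start < min_length:
        return None
    return _slice(read, start, end)


# ---------------------------------------------------------------------------
# Organelle screening
# ---------------------------------------------------------------------------

def screen_organelle(read: SeqRecord, organelle_hits: list[AlignmentHit],
                     max_evalue: float = 1e-20,
                     min_coverage: float = 0.80) -> bool:
    """True when some organelle hit passes both the E-value cutoff and the
    per-hit query-coverage rule."""
    L = len(read)
    for h in organelle_hits:
        if h.evalue <= max_evalue and (h.query_end - h.query_start) >= min_coverage * L:
            return True
    return False


def clone_contaminated(flags_by_end: dict[str, bool]) -> bool:
    """A clone is contaminated when either end is flagged."""
    return any(flags_by_end.values())
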