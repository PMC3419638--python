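"""Synthetic genomes, BAC clones and end reads with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome reference genome related to a query genome by block-wise
expansion/contraction (mean expansion factor 1.3), inversions and
translocations; BAC clones with gel-calibrated insert sizes (mean 125 kb,
bounded 29-293 kb); paired end reads around 944 bp with 3'-decaying
quality and substitution errors; a small rate of organelle-contaminated
clones; and an LTR-retrotransposon-dominated repeat landscape.

Every random draw flows from a single master seed through named
substreams, so the same (config, seed) always yields byte-identical
datasets and any stage can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .io_formats import Config, SeqRecord, revcomp, write_fasta, write_fastq
from .repeat_summary import RepeatTaxonomy

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream tags for the master seed
_S_GENOME, _S_PLAN, _S_REF, _S_CLONES, _S_READS, _S_CONTAM, _S_ORGANELLE, _S_LIB = range(1, 9)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    return bytes(_BASES[codes]).decode("ascii")


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitution-only divergence: each base replaced with one of the
    three alternatives with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    if len(idx):
        # map base -> code, add 1..3 mod 4 to guarantee a change
        code = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            code[b] = i
        new = (code[arr[idx]] + rng.integers(1, 4, size=len(idx))) % 4
        arr[idx] = _BASES[new]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Repeat library
# ---------------------------------------------------------------------------

# (family, consensus length, share of planted repeat bases); shares follow
# the LTR-dominated composition of grass genomes: Copia and Gypsy carry the
# bulk, DNA transposons ~11%, the rest traces.
_DEFAULT_FAMILIES = [
    ("Copia", 5000, 0.41),
    ("Gypsy", 5500, 0.44),
    ("L1", 3000, 0.012),
    ("RTE", 2500, 0.010),
    ("SINE", 250, 0.002),
    ("SINE2/tRNA", 250, 0.002),
    ("EnSpm", 2000, 0.030),
    ("Harbinger", 1500, 0.020),
    ("Helitron", 1800, 0.018),
    ("MuDr", 1600, 0.020),
    ("hAT", 1400, 0.016),
    ("Caulimoviridae", 1200, 0.008),
    ("Satellite", 300, 0.012),
]


def generate_repeat_library(seed: int, gc: float = 0.44) -> list[SeqRecord]:
    """Random consensus sequences, one per default repeat family."""
    rng = _rng(seed, _S_LIB)
    return [SeqRecord(fam, random_sequence(rng, length, gc), "synthetic consensus")
            for fam, length, _ in _DEFAULT_FAMILIES]


@dataclass
class PlantedRepeat:
    chrom: str
    start: int
    end: int
    family: str


def generate_query_genome(n_chroms: int, chrom_len: int, gc: float,
                          repeat_library: list[SeqRecord] | None,
                          repeat_density: float, seed: int,
                          divergence: tuple[float, float] = (0.02, 0.15),
                          max_insert: int = 293_000,
                          ) -> tuple[dict[str, str], list[PlantedRepeat]]:
    """I.i.d. background at the requested GC with repeat copies planted at
    exponentially spaced positions, each copy independently diverged."""
    if chrom_len < 10 * max_insert:
        raise ValueError(f"chromosome length {chrom_len} < 10x max insert size")
    if repeat_density > 0.9:
        raise ValueError("repeat_density > 0.9 would leave no unique sequence")
    rng = _rng(seed, _S_GENOME)
    genome: dict[str, str] = {}
    planted: list[PlantedRepeat] = []
    lib = repeat_library or []
    if repeat_density > 0 and not lib:
        raise ValueError("repeat_density > 0 requires a repeat library")
    weights = None
    if lib:
        by_id = {r.id: r for r in lib}
        fams = [(f, l, w) for f, l, w in _DEFAULT_FAMILIES if f in by_id]
        if not fams:
            fams = [(r.id, len(r.sequence), 1.0) for r in lib]
        wsum = sum(w for _, _, w in fams)
        # pick families so the *base* composition follows the shares:
        # selection probability proportional to share / copy length
        sel = np.array([w / wsum / l for _, l, w in fams])
        sel /= sel.sum()
        mean_copy = sum((w / wsum) * l for _, l, w in fams) / sum(
            (w / wsum) for _, l, w in fams)
        weights = (fams, sel, mean_copy)
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1:02d}"
        arr = bytearray(random_sequence(rng, chrom_len, gc), "ascii")
        if repeat_density > 0 and weights is not None:
            fams, sel, mean_copy = weights
            # expected copy length under the selection distribution
            exp_len = float(sum(sel[i] * fams[i][1] for i in range(len(fams))))
            mean_gap = exp_len * (1 - repeat_density) / repeat_density
            pos = int(rng.exponential(mean_gap))
            while pos < chrom_len:
                fi = int(rng.choice(len(fams), p=sel))
                fam, clen, _ = fams[fi]
                if pos + clen > chrom_len:
                    break
                d = rng.uniform(*divergence)
                copy = mutate(rng, by_id[fam].sequence, d)
                arr[pos:pos + clen] = copy.encode("ascii")
                planted.append(PlantedRepeat(chrom, pos, pos + clen, fam))
                pos += clen + int(rng.exponential(mean_gap))
        genome[chrom] = arr.decode("ascii")
    return genome, planted


# ---------------------------------------------------------------------------
# Rearrangement plan and reference derivation
# ---------------------------------------------------------------------------

@dataclass
class Block:
    query_chrom: str
    query_start: int
    query_end: int
    ref_chrom: str
    scale_factor: float
    inverted: bool
    # filled in by derive_reference_genome
    ref_start: int = -1
    ref_end: int = -1

    @property
    def translocated(self) -> bool:
        return self.ref_chrom != self.query_chrom


@dataclass
class RearrangementPlan:
    blocks: list[Block]

    def validate(self, genome: dict[str, str]) -> None:
        """Blocks must tile every query chromosome without gap or overlap."""
        by_chrom: dict[str, list[Block]] = {}
        for b in self.blocks:
            if not 0.1 <= b.scale_factor <= 10:
                raise ValueError(f"scale factor {b.scale_factor} out of [0.1, 10]")
            by_chrom.setdefault(b.query_chrom, []).append(b)
        if set(by_chrom) != set(genome):
            raise ValueError("plan chromosomes do not match the query genome")
        for chrom, blocks in by_chrom.items():
            blocks = sorted(blocks, key=lambda b: b.query_start)
            pos = 0
            for b in blocks:
                if b.query_start != pos:
                    raise ValueError(f"plan does not tile {chrom} at {pos}")
                pos = b.query_end
            if pos != len(genome[chrom]):
                raise ValueError(f"plan stops at {pos} on {chrom}")

    def block_at(self, chrom: str, pos: int) -> Block:
        for b in self.blocks:
            if b.query_chrom == chrom and b.query_start <= pos < b.query_end:
                return b
        raise KeyError(f"no block covers {chrom}:{pos}")

    def query_to_ref(self, chrom: str, pos: int) -> tuple[str, int, bool]:
        """Approximate image of a query position on the reference (linear
        interpolation within its block).  Returns (ref_chrom, ref_pos,
        inverted)."""
        b = self.block_at(chrom, pos)
        frac = (pos - b.query_start) / (b.query_end - b.query_start)
        if b.inverted:
            rpos = b.ref_end - frac * (b.ref_end - b.ref_start)
        else:
            rpos = b.ref_start + frac * (b.ref_end - b.ref_start)
        return b.ref_chrom, int(rpos), b.inverted


def make_plan(genome: dict[str, str], seed: int, *, block_length: int = 400_000,
              mean_expansion: float = 1.30, expansion_sd: float = 0.15,
              inversion_rate: float = 0.05,
              translocation_rate: float = 0.05) -> RearrangementPlan:
    """Tile the query genome into blocks with lognormal-free scale factors
    drawn from a truncated normal around ``mean_expansion``."""
    rng = _rng(seed, _S_PLAN)
    chroms = list(genome)
    blocks: list[Block] = []
    for chrom in chroms:
        L = len(genome[chrom])
        n_blocks = max(1, round(L / block_length))
        edges = np.linspace(0, L, n_blocks + 1).astype(int)
        for qs, qe in zip(edges[:-1], edges[1:]):
            scale = float(np.clip(rng.normal(mean_expansion, expansion_sd), 0.1, 10))
            inverted = bool(rng.random() < inversion_rate)
            ref_chrom = chrom
            if len(chroms) > 1 and rng.random() < translocation_rate:
                others = [c for c in chroms if c != chrom]
                ref_chrom = others[int(rng.integers(len(others)))]
            blocks.append(Block(chrom, int(qs), int(qe), ref_chrom, scale, inverted))
    plan = RearrangementPlan(blocks)
    plan.validate(genome)
    return plan


def _split_chunks(rng: np.random.Generator, total: int, chunk_mean: int) -> np.ndarray:
    """Partition ``total`` bases into roughly exponential chunk sizes."""
    n = max(1, round(total / chunk_mean))
    raw = rng.exponential(1.0, size=n)
    sizes = np.floor(raw / raw.sum() * total).astype(int)
    sizes[0] += total - sizes.sum()
    return sizes[sizes > 0]


def derive_reference_genome(query: dict[str, str], plan: RearrangementPlan,
                            seed: int, *, indel_chunk_mean: int = 5_000
                            ) -> dict[str, str]:
    """Realise the plan: copy each block to its reference chromosome in
    plan order, expanding (>1) by inserting random-sequence tracts at
    uniform positions, contracting (<1) by deleting tracts at uniform
    positions, and reverse-complementing inverted blocks.

    Length changes happen in contiguous chunks (exponential sizes, mean
    ``indel_chunk_mean``), mimicking repeat/indel tracts accumulating
    between conserved stretches: most sub-kilobase reads taken from the
    query still match the reference contiguously, while block spans grow
    or shrink by the scale factor.  Block reference coordinates are
    recorded in place.
    """
    plan.validate(query)
    rng = _rng(seed, _S_REF)
    pieces: dict[str, list[str]] = {c: [] for c in query}
    lengths: dict[str, int] = {c: 0 for c in query}
    for b in plan.blocks:
        seg = query[b.query_chrom][b.query_start:b.query_end]
        blen = len(seg)
        target = round(b.scale_factor * blen)
        if target > blen:
            chunks = _split_chunks(rng, target - blen, indel_chunk_mean)
            sites = np.sort(rng.integers(0, blen + 1, size=len(chunks)))
            parts, prev = [], 0
            for site, clen in zip(sites, chunks):
                parts.append(seg[prev:site])
                parts.append(random_sequence(rng, int(clen), 0.44))
                prev = site
            parts.append(seg[prev:])
            seg = "".join(parts)
        elif target < blen:
            chunks = _split_chunks(rng, blen - target, indel_chunk_mean)
            # deletion tract i starts after starts[i] kept bases
            starts = np.sort(rng.integers(0, target + 1, size=len(chunks)))
            parts, ptr, kept = [], 0, 0
            for start, clen in zip(starts, chunks):
                take = start - kept
                parts.append(seg[ptr:ptr + take])
                ptr += take + int(clen)
                kept += take
            parts.append(seg[ptr:])
            seg = "".join(parts)
        if b.inverted:
            seg = revcomp(seg)
        b.ref_start = lengths[b.ref_chrom]
        b.ref_end = b.ref_start + len(seg)
        pieces[b.ref_chrom].append(seg)
        lengths[b.ref_chrom] += len(seg)
    return {c: "".join(pieces[c]) for c in query}


# ---------------------------------------------------------------------------
# Clones and reads
# ---------------------------------------------------------------------------

ORGANELLE_LABEL = "chloroplast"


@dataclass
class BACClone:
    clone_id: str
    insert_size: int
    origin_chrom: str          # query chromosome, or the organelle label
    origin_start: int
    origin_end: int

    @property
    def contaminated(self) -> bool:
        return self.origin_chrom == ORGANELLE_LABEL


def sample_bac_clones(query: dict[str, str], n: int, seed: int, *,
                      insert_mean: float = 125_000.0,
                      insert_sd: float = 35_000.0,
                      insert_min: int = 29_000,
                      insert_max: int = 293_000) -> list[BACClone]:
    """Clone positions uniform over the genome (chromosomes weighted by
    length); insert sizes from a truncated normal calibrated so that the
    sample mean is ~125 kb and ~88% of inserts exceed 90 kb."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _rng(seed, _S_CLONES)
    chroms = list(query)
    lens = np.array([len(query[c]) for c in chroms], dtype=float)
    a = (insert_min - insert_mean) / insert_sd
    b = (insert_max - insert_mean) / insert_sd
    sizes = stats.truncnorm.rvs(a, b, loc=insert_mean, scale=insert_sd,
                                size=n, random_state=rng)
    clones = []
    for i in range(n):
        size = int(round(sizes[i]))
        ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
        chrom = chroms[ci]
        start = int(rng.integers(0, len(query[chrom]) - size + 1))
        clones.append(BACClone(f"BAC{i + 1:04d}", size, chrom, start, start + size))
    return clones


def inject_contamination(clones: list[BACClone], organelle_length: int,
                         rate: float, seed: int) -> list[BACClone]:
    """Independently replace each clone with an organelle-derived insert
    with probability ``rate`` (the organelle is treated as circular)."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = _rng(seed, _S_CONTAM)
    out = []
    for clone in clones:
        if rng.random() < rate:
            start = int(rng.integers(0, organelle_length))
            out.append(BACClone(clone.clone_id, clone.insert_size,
                                ORGANELLE_LABEL, start, start + clone.insert_size))
        else:
            out.append(clone)
    return out


def _quality_profile(length: int) -> list[int]:
    """High, flat quality over the first 60% of the read, decaying linearly
    to Q25 at the 3' end — a coarse trace-read shape."""
    q = np.full(length, 45.0)
    knee = int(0.6 * length)
    if length > knee:
        q[knee:] = np.linspace(45.0, 25.0, length - knee)
    return [int(round(x)) for x in q]


def extract_bes(clone: BACClone, insert_seq: str, seed: int, *,
                read_mean: float = 944.0, read_sd: float = 150.0,
                read_min: int = 312,
                error_rate: float = 0.005) -> tuple[SeqRecord, SeqRecord]:
    """Forward read from the 5' end of the insert, reverse read as the
    reverse complement of the 3' end, both with 3'-decaying quality and
    substitution errors at ``error_rate``."""
    if len(insert_seq) < 2 * read_min:
        raise ValueError(f"insert of {clone.clone_id} shorter than 2x minimum read")
    rng = _rng(seed, _S_READS)
    cap = len(insert_seq) // 2
    lengths = np.clip(rng.normal(read_mean, read_sd, size=2), read_min, cap)
    lf, lr = int(lengths[0]), int(lengths[1])
    fwd = mutate(rng, insert_seq[:lf], error_rate)
    rev = mutate(rng, revcomp(insert_seq[-lr:]), error_rate)
    return (SeqRecord(f"{clone.clone_id}.f", fwd, quality=_quality_profile(lf)),
            SeqRecord(f"{clone.clone_id}.r", rev, quality=_quality_profile(lr)))


# ---------------------------------------------------------------------------
# Whole-dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    plan: RearrangementPlan | None
    clones: list[BACClone]
    planted_repeats: list[PlantedRepeat]
    contaminated_clone_ids: list[str]
    planted_mean_expansion: float
    planted_classes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "planted_mean_expansion": self.planted_mean_expansion,
            "contaminated_clone_ids": self.contaminated_clone_ids,
            "clones": [asdict(c) for c in self.clones],
            "planted_repeats": [asdict(r) for r in self.planted_repeats],
            "planted_classes": self.planted_classes,
            "plan": [asdict(b) for b in self.plan.blocks] if self.plan else None,
        }
        return json.dumps(payload, indent=1)


@dataclass
class Dataset:
    outdir: Path
    reads_path: Path
    reference_path: Path
    organelle_path: Path
    repeats_path: Path | None
    inserts_path: Path
    truth_path: Path
    truth: TruthSet
    query_genome: dict[str, str]
    reference_genome: dict[str, str]
    reads: list[SeqRecord]


def make_dataset(config: Config, outdir: str | Path) -> Dataset:
    """Generate a full dataset (reads, reference, insert table, truth) in
    ``outdir``, reproducibly from the config's seed."""
    seed = config.require_seed()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    library = generate_repeat_library(seed, config.gc_content) \
        if config.repeat_density > 0 else None
    query, planted = generate_query_genome(
        config.n_chromosomes, config.chromosome_length, config.gc_content,
        library, config.repeat_density, seed,
        (config.repeat_divergence_min, config.repeat_divergence_max),
        config.insert_max)
    plan = make_plan(query, seed, block_length=config.block_length,
                     mean_expansion=config.mean_expansion,
                     expansion_sd=config.expansion_sd,
                     inversion_rate=config.inversion_rate,
                     translocation_rate=config.translocation_rate)
    reference = derive_reference_genome(query, plan, seed)

    org_rng = _rng(seed, _S_ORGANELLE)
    organelle = random_sequence(org_rng, config.organelle_length, 0.37)

    clones = sample_bac_clones(query, config.n_clones, seed,
                               insert_mean=config.insert_mean,
                               insert_sd=config.insert_sd,
                               insert_min=config.insert_min,
                               insert_max=config.insert_max)
    clones = inject_contamination(clones, config.organelle_length,
                                  config.contamination_rate, seed)

    reads: list[SeqRecord] = []
    for i, clone in enumerate(clones):
        if clone.contaminated:
            circular = organelle * (clone.insert_size // len(organelle) + 2)
            insert_seq = circular[clone.origin_start:
                                  clone.origin_start + clone.insert_size]
        else:
            insert_seq = query[clone.origin_chrom][clone.origin_start:clone.origin_end]
        # per-clone read substream, derived from the master seed
        fwd, rev = extract_bes(clone, insert_seq, seed * 100_003 + i,
                               read_mean=config.read_length_mean,
                               read_sd=config.read_length_sd,
                               read_min=config.read_length_min,
                               error_rate=config.base_error_rate)
        reads.extend([fwd, rev])

    truth = TruthSet(plan, clones, planted,
                     [c.clone_id for c in clones if c.contaminated],
                     config.mean_expansion)

    reads_path = outdir / "reads.fastq"
    reference_path = outdir / "reference.fasta"
    organelle_path = outdir / "organelle.fasta"
    inserts_path = outdir / "inserts.tsv"
    truth_path = outdir / "truth.json"
    write_fastq(reads, reads_path)
    write_fasta([SeqRecord(c, reference[c]) for c in reference], reference_path)
    write_fasta([SeqRecord(ORGANELLE_LABEL, organelle)], organelle_path)
    repeats_path = None
    if library:
        repeats_path = outdir / "repeat_library.fasta"
        write_fasta(library, repeats_path)
    with open(inserts_path, "w") as fh:
        fh.write("clone_id\tinsert_size\n")
        for c in clones:
            fh.write(f"{c.clone_id}\t{c.insert_size}\n")
    truth_path.write_text(truth.to_json())
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    return Dataset(outdir, reads_path, reference_path, organelle_path,
                   repeats_path, inserts_path, truth_path, truth,
                   query, reference, reads)


# ---------------------------------------------------------------------------
# Direct class planting (for classifier-recovery experiments)
# ---------------------------------------------------------------------------

def simulate_class_library(seed: int, counts: dict[str, int] | None = None, *,
                           n_chroms: int = 3, chrom_len: int = 1_500_000,
                           gc: float = 0.44,
                           read_min: int = 400, read_max: int = 1000,
                           ) -> tuple[dict[str, str], list[SeqRecord],
                                      dict[str, str], dict[str, int]]:
    """Plant clones of known synteny class directly on a fresh reference.

    Pairs are constructed from reference coordinates chosen to realise each
    class definition exactly (orientation, span band, chromosome identity,
    hit multiplicity), with the forward/reverse roles of the two ends
    swapped at random.  Returns (reference, reads, truth labels by clone,
    insert sizes by clone).
    """
    if counts is None:
        counts = {"C1": 10, "C2": 4, "C3": 4, "C4": 4, "C5": 4,
                  "C6": 4, "C7": 4, "C8": 4, "C9": 4}
    rng = np.random.default_rng([seed, 77])
    reference = {f"chr{i + 1:02d}": random_sequence(rng, chrom_len, gc)
                 for i in range(n_chroms)}
    chroms = list(reference)
    # a duplicated cassette gives multi-hit (C8) ends; paste the same 2 kb
    # sequence at three well-separated sites
    cassette = random_sequence(rng, 2000, gc)
    dup_sites = [(chroms[0], 100_000), (chroms[1 % n_chroms], 700_000),
                 (chroms[2 % n_chroms], 1_200_000)]
    for chrom, pos in dup_sites:
        s = reference[chrom]
        reference[chrom] = s[:pos] + cassette + s[pos + 2000:]

    def rand_len() -> int:
        return int(rng.integers(read_min, read_max + 1))

    def clear_of_cassette(chrom: str, *intervals: tuple[int, int]) -> bool:
        for site_chrom, site_pos in dup_sites:
            if site_chrom != chrom:
                continue
            for s, e in intervals:
                if s < site_pos + 2000 and e > site_pos:
                    return False
        return True

    def ref_read(chrom: str, pos: int, length: int, strand: str) -> str:
        seg = reference[chrom][pos:pos + length]
        return seg if strand == "+" else revcomp(seg)

    def random_read(length: int) -> str:
        return random_sequence(rng, length, gc)

    reads: list[SeqRecord] = []
    truth: dict[str, str] = {}
    inserts: dict[str, int] = {}
    clone_no = 0

    def emit(clone_id: str, fwd: str, rev: str) -> None:
        reads.append(SeqRecord(f"{clone_id}.f", fwd))
        reads.append(SeqRecord(f"{clone_id}.r", rev))

    for label in sorted(counts):
        for _ in range(counts[label]):
            clone_no += 1
            clone_id = f"PL{clone_no:04d}"
            truth[clone_id] = label
            lu, ld = rand_len(), rand_len()
            chrom = chroms[int(rng.integers(n_chroms))]
            if label in ("C1", "C2", "C3", "C4", "C5", "X1", "X2", "X3", "X4"):
                if label in ("C1", "C2", "X4"):
                    span = int(rng.integers(40_000, 260_000))
                elif label in ("C3", "C4", "C5"):
                    span = int(rng.integers(320_000, 700_000))
                else:  # X1-X3: span below the 20 kb floor
                    span = int(rng.integers(max(lu + ld + 200, 4_000), 18_000))
                while True:
                    u = int(rng.integers(0, chrom_len - span - 1))
                    d = u + span - ld
                    if clear_of_cassette(chrom, (u, u + lu), (d, d + ld)):
                        break
                if label in ("C1", "C3", "X1"):      # opposite-in: + then -
                    up, down = ref_read(chrom, u, lu, "+"), ref_read(chrom, d, ld, "-")
                elif label in ("C2", "C4", "X2"):    # same orientation
                    up, down = ref_read(chrom, u, lu, "+"), ref_read(chrom, d, ld, "+")
                else:                                # opposite-out: - then +
                    up, down = ref_read(chrom, u, lu, "-"), ref_read(chrom, d, ld, "+")
                inserts[clone_id] = span
                # the upstream end is the forward read half the time
                if rng.random() < 0.5:
                    emit(clone_id, up, down)
                else:
                    emit(clone_id, down, up)
            elif label == "C6":
                other = chroms[(chroms.index(chrom) + 1) % n_chroms]
                while True:
                    p1 = int(rng.integers(0, chrom_len - lu))
                    if clear_of_cassette(chrom, (p1, p1 + lu)):
                        break
                while True:
                    p2 = int(rng.integers(0, chrom_len - ld))
                    if clear_of_cassette(other, (p2, p2 + ld)):
                        break
                emit(clone_id, ref_read(chrom, p1, lu, "+"),
                     ref_read(other, p2, ld, "-"))
                inserts[clone_id] = int(rng.integers(40_000, 260_000))
            elif label in ("C7", "C8"):
                if label == "C7":
                    while True:
                        pos = int(rng.integers(0, chrom_len - lu))
                        if clear_of_cassette(chrom, (pos, pos + lu)):
                            break
                    aligned = ref_read(chrom, pos, lu, "+")
                else:
                    dchrom, dpos = dup_sites[int(rng.integers(len(dup_sites)))]
                    off = int(rng.integers(0, 2000 - min(lu, 1800)))
                    aligned = ref_read(dchrom, dpos + off, min(lu, 1800), "+")
                if rng.random() < 0.5:
                    emit(clone_id, aligned, random_read(ld))
                else:
                    emit(clone_id, random_read(ld), aligned)
                inserts[clone_id] = int(rng.integers(40_000, 260_000))
            elif label == "C9":
                emit(clone_id, random_read(lu), random_read(ld))
                inserts[clone_id] = int(rng.integers(40_000, 260_000))
            else:
                raise ValueError(f"cannot plant class {label!r}")
    return reference, reads, truth, inserts
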