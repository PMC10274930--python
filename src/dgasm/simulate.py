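"""Diploid/polyploid genome and read simulator with ground truth.

The generator emulates the data regime a hybrid assembler faces: a set of
haplotypes that differ by SNVs, exact interspersed repeats shared by all
haplotypes, telomere motifs stamped on chromosome ends, accurate reads
(error-free by default; base correction is out of scope) and ultra-long
noisy-capable reads 5-10x longer. Truth provenance travels in read names so
any downstream stage can be scored without auxiliary files.

A repeat with a single locus doubles as an exact homozygous segment: the
segment is identical across haplotypes (SNVs are excluded from it) without
being repeated along the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._kmer import revcomp
from .errors import ValidationError
from .formats import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class RepeatSpec:
    """An exact repeat unit stamped at the given (chrom, pos) loci."""

    unit_len: int
    loci: list  # list of (chrom_index, position)
    divergence: float = 0.0

    @property
    def copy_number(self) -> int:
        return len(self.loci)


@dataclass
class SimGenomeSpec:
    ploidy: int = 2
    chrom_lengths: list = field(default_factory=lambda: [100_000])
    het_rate: float = 0.001
    repeat_spec: list = field(default_factory=list)
    telomere_motif: str = "TTAGGG"
    telomere_copies: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")
        if not (0.0 <= self.het_rate <= 0.05):
            raise ValidationError("het_rate must lie in [0, 0.05]")
        tel = len(self.telomere_motif) * self.telomere_copies
        for rep in self.repeat_spec:
            for chrom, pos in rep.loci:
                if chrom >= len(self.chrom_lengths):
                    raise ValidationError(f"repeat locus on unknown chromosome {chrom}")
                if pos < tel or pos + rep.unit_len > self.chrom_lengths[chrom] - tel:
                    raise ValidationError(
                        f"repeat at chr{chrom}:{pos} overlaps a chromosome end")


@dataclass
class SimReadSpec:
    role: str  # 'accurate' | 'ultralong'
    mean_len: int
    len_sd: int
    min_len: int
    coverage: float
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.role not in {"accurate", "ultralong"}:
            raise ValidationError(f"unknown read role {self.role!r}")
        if self.coverage <= 0:
            raise ValidationError("coverage must be > 0")
        if self.min_len <= 0 or self.mean_len <= 0:
            raise ValidationError("lengths must be positive")


@dataclass
class SimGenome:
    spec: SimGenomeSpec
    haplotypes: list  # [hap][chrom] -> sequence string
    snv_table: list   # (hap, chrom, pos, ref, alt)

    @property
    def ploidy(self) -> int:
        return len(self.haplotypes)

    def haplotype_size(self, hap: int) -> int:
        return sum(len(c) for c in self.haplotypes[hap])


@dataclass
class TruthRead:
    record: SeqRecord
    hap: int
    chrom: int
    start: int
    end: int
    strand: str


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome(spec: SimGenomeSpec) -> SimGenome:
    """Generate ploidy haplotypes differing only at recorded SNV loci."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tel = (spec.telomere_motif * spec.telomere_copies)
    tel_len = len(tel)
    tel_start = np.frombuffer(tel.encode(), np.uint8)
    tel_end = np.frombuffer(revcomp(tel).encode(), np.uint8)
    code = {65: 0, 67: 1, 71: 2, 84: 3}

    bases: list[np.ndarray] = []
    frozen: list[np.ndarray] = []  # per chrom: bool mask of SNV-excluded sites
    for length in spec.chrom_lengths:
        if length < 2 * tel_len + 1:
            raise ValidationError("chromosome shorter than its telomere stamps")
        chrom = rng.integers(0, 4, size=length, dtype=np.uint8)
        mask = np.zeros(length, dtype=bool)
        chrom[:tel_len] = [code[b] for b in tel_start]
        chrom[length - tel_len:] = [code[b] for b in tel_end]
        mask[:tel_len] = True
        mask[length - tel_len:] = True
        bases.append(chrom)
        frozen.append(mask)
    for rep in spec.repeat_spec:
        unit = rng.integers(0, 4, size=rep.unit_len, dtype=np.uint8)
        for chrom, pos in rep.loci:
            copy = unit.copy()
            if rep.divergence > 0:
                hit = rng.random(rep.unit_len) < rep.divergence
                copy[hit] = (copy[hit] + rng.integers(1, 4, hit.sum())) % 4
            bases[chrom][pos : pos + rep.unit_len] = copy
            frozen[chrom][pos : pos + rep.unit_len] = True

    haplotypes: list[list[str]] = [[_decode(c) for c in bases]]
    snv_table: list[tuple] = []
    for hap in range(1, spec.ploidy):
        chroms = []
        for ci, base in enumerate(bases):
            hapc = base.copy()
            hit = np.nonzero((rng.random(len(base)) < spec.het_rate) & ~frozen[ci])[0]
            shifts = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
            for pos, shift in zip(hit.tolist(), shifts.tolist()):
                ref = int(base[pos])
                alt = (ref + shift) % 4
                hapc[pos] = alt
                snv_table.append((hap, ci, int(pos), "ACGT"[ref], "ACGT"[alt]))
            chroms.append(_decode(hapc))
        haplotypes.append(chroms)
    return SimGenome(spec, haplotypes, snv_table)


def read_name(role: str, serial: int, hap: int, chrom: int, start: int,
              end: int, strand: str) -> str:
    return f"{role[:2]}{serial:06d}_h{hap}_c{chrom}_{start}_{end}_{strand}"


def parse_read_name(name: str) -> tuple[int, int, int, int, str]:
    """(hap, chrom, start, end, strand) recovered from a simulated read name."""
    parts = name.split("_")
    return (int(parts[1][1:]), int(parts[2][1:]), int(parts[3]),
            int(parts[4]), parts[5])


def simulate_reads(genome: SimGenome, spec: SimReadSpec) -> list[TruthRead]:
    """Sample reads uniformly per haplotype; truncated-normal lengths.

    The read count per (haplotype, chromosome) is coverage x length /
    mean_len, so total bases track the requested coverage; with error_rate=0
    every read is an exact (possibly reverse-complemented) substring of its
    haplotype.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    reads: list[TruthRead] = []
    serial = 0
    for hap in range(genome.ploidy):
        for chrom, seq in enumerate(genome.haplotypes[hap]):
            L = len(seq)
            if spec.min_len > L:
                raise ValidationError(
                    f"min_len {spec.min_len} exceeds chromosome length {L}")
            n = max(1, int(round(spec.coverage * L / spec.mean_len)))
            lens = rng.normal(spec.mean_len, spec.len_sd, size=n)
            lens = np.clip(np.rint(lens), spec.min_len, L).astype(np.int64)
            starts = rng.integers(0, L - lens + 1)
            strands = rng.integers(0, 2, size=n)
            for ln, st, fw in zip(lens.tolist(), starts.tolist(), strands.tolist()):
                end = st + ln
                frag = seq[st:end]
                if spec.error_rate > 0:
                    codes = np.frombuffer(frag.encode(), np.uint8).copy()
                    hit = np.nonzero(rng.random(ln) < spec.error_rate)[0]
                    if hit.size:
                        lut = np.zeros(256, np.uint8)
                        for b, v in zip(b"ACGTN", [0, 1, 2, 3, 0]):
                            lut[b] = v
                        vals = lut[codes[hit]]
                        vals = (vals + rng.integers(1, 4, hit.size, dtype=np.uint8)) % 4
                        codes[hit] = _BASES[vals]
                    frag = codes.tobytes().decode("ascii")
                strand = "+" if fw == 0 else "-"
                if strand == "-":
                    frag = revcomp(frag)
                name = read_name(spec.role, serial, hap, chrom, st, end, strand)
                qual = "I" * ln if spec.role == "ultralong" else None
                reads.append(TruthRead(SeqRecord(name, frag, qual),
                                       hap, chrom, st, end, strand))
                serial += 1
    return reads


def records(reads: list[TruthRead]) -> list[SeqRecord]:
    return [r.record for r in reads]


def write_truth_table(reads: list[TruthRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\thap\tchrom\tstart\tend\tstrand\n")
        for r in reads:
            fh.write(f"{r.record.id}\t{r.hap}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}\n")


def write_snv_table(genome: SimGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("hap\tchrom\tpos\tref\talt\n")
        for hap, chrom, pos, ref, alt in genome.snv_table:
            fh.write(f"{hap}\t{chrom}\t{pos}\t{ref}\t{alt}\n")


def canonical_repeat_fixture(seed: int = 42):
    """The canonical UL-resolvable repeat fixture: a diploid chromosome with
    het SNVs and two exact copies of a repeat longer than any accurate read
    but comfortably spanned by ultra-long reads. Accurate-read-only assembly
    must tangle (and fragment) at the repeat; the hybrid pipeline walks
    through it.

    Returns (genome_spec, accurate_spec, ultralong_spec).
    """
    gspec = SimGenomeSpec(
        ploidy=2,
        chrom_lengths=[140_000],
        het_rate=0.005,
        repeat_spec=[RepeatSpec(18_000, [(0, 30_000), (0, 85_000)])],
        seed=seed,
    )
    hifi = SimReadSpec("accurate", mean_len=6_000, len_sd=2_000, min_len=2_000,
                       coverage=10.0, error_rate=0.0, seed=seed + 1)
    ul = SimReadSpec("ultralong", mean_len=35_000, len_sd=8_000, min_len=18_000,
                     coverage=12.0, error_rate=0.0, seed=seed + 2)
    return gspec, hifi, ul
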