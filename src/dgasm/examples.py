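"""Worked-example fixtures, constructed programmatically.

``contained_read_example`` builds a concrete two-haplotype layout of twelve
accurate reads (h1-h12) and seven ultra-long reads (u1-u7) in which h11 and
h12 are contained in the long read h3. h3 carries haplotype-1-specific
sequence at both tips, so the haplotype-2 walk cannot enter it: h12 is the
only bridge across the middle of the shared segment for haplotype 2 (the
critical contained read, covered by u6 and u7), while h11 is redundant.
The (h5,h8) junction is covered by the ultra-long reads u4 and u5, so its
edge weight is 2.

``incorporation_example`` builds a seven-unitig backbone (two haplotype arms
around two shared segments plus a short terminal unitig no ultra-long read
reaches) and the integer sequences whose contigs cover every unitig except
that terminal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import SeqRecord
from .graph import StringGraph
from .overlap import OverlapParams
from .ul_align import IntegerSequence, ULAlignParams

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class ContainedReadExample:
    reads: list          # SeqRecord h1..h12
    ul_reads: list       # SeqRecord u1..u7
    haplotypes: list     # the two truth haplotype sequences
    contained: set       # expected contained read ids
    critical: set        # expected critical contained reads
    removable: set       # expected removable contained reads
    support_edge: tuple  # the (h5, h8) edge
    overlap_params: OverlapParams
    align_params: ULAlignParams


def contained_read_example(seed: int = 0) -> ContainedReadExample:
    rng = np.random.default_rng(seed)
    a1 = _rand_seq(rng, 1200)   # haplotype-1 left flank
    a2 = _rand_seq(rng, 1200)   # haplotype-2 left flank
    mid = _rand_seq(rng, 3600)  # exact homozygous middle
    b1 = _rand_seq(rng, 2200)   # haplotype-1 right flank
    b2 = _rand_seq(rng, 2200)   # haplotype-2 right flank
    h1seq = a1 + mid + b1
    h2seq = a2 + mid + b2

    cuts1 = {
        "h1": (0, 1000), "h2": (700, 1950), "h3": (1000, 4900),
        "h4": (4600, 5500), "h5": (5200, 6200), "h8": (5900, 7000),
        "h11": (3200, 4200),  # = mid[2000:3000], contained in h3
    }
    cuts2 = {
        "h9": (0, 1000), "h10": (700, 2100),
        "h12": (1850, 3000),  # = mid[650:1800], contained in h3, critical
        "h6": (2700, 4900), "h7": (4500, 5800),
    }
    reads = [SeqRecord(n, h1seq[s:e]) for n, (s, e) in cuts1.items()]
    reads += [SeqRecord(n, h2seq[s:e]) for n, (s, e) in cuts2.items()]
    reads.sort(key=lambda r: int(r.id[1:]))

    ul_cuts = {
        "u1": (1, 0, 2500), "u2": (1, 800, 3800), "u3": (1, 2000, 5000),
        "u4": (1, 3800, 6600), "u5": (1, 4400, 6800),
        "u6": (2, 300, 3600), "u7": (2, 1400, 5600),
    }
    ul_reads = [SeqRecord(n, (h1seq if hap == 1 else h2seq)[s:e])
                for n, (hap, s, e) in ul_cuts.items()]

    return ContainedReadExample(
        reads=reads,
        ul_reads=ul_reads,
        haplotypes=[h1seq, h2seq],
        contained={"h11", "h12"},
        critical={"h12"},
        removable={"h11"},
        support_edge=("h5", "h8"),
        overlap_params=OverlapParams(k=21, min_ovlp=250, max_div=0.0),
        align_params=ULAlignParams(),
    )


@dataclass
class ContainedRescueFixture:
    """Deterministically tiled diploid instance of the contained-read stress."""

    genome: object             # SimGenome
    reads: list                # accurate SeqRecords (tiling + designed reads)
    ul_reads: list             # ultra-long SeqRecords (tiling)
    critical: str              # the contained read that bridges haplotype 2
    spanner: str               # the haplotype-1 read containing it
    overlap_params: OverlapParams
    align_params: ULAlignParams


def contained_rescue_fixture(seed: int = 0) -> ContainedRescueFixture:
    """The het + UL-resolvable-repeat fixture for contained-read rescue.

    The genome is a diploid 150 kb chromosome with two exact 18 kb repeat
    copies (longer than any accurate read, spanned by ultra-long reads) and
    one exact 12 kb homozygous corridor. Accurate reads are tiled
    deterministically (6 kb reads, 2 kb stride) with the corridor interior
    left uncovered except for two designed reads that reproduce the
    contained-read mechanism: a 16 kb haplotype-1 spanner crossing the whole
    corridor with haplotype-1 flanks on both tips, and a 7 kb purely
    homozygous bridge contained in it. Haplotype 1 walks the corridor through
    the spanner; haplotype 2 can only walk it through the bridge, so dropping
    all contained reads severs the haplotype-2 tail, while rescue (the bridge
    is covered by several ultra-long reads and is junction-essential) restores
    it.
    """
    from .simulate import RepeatSpec, SimGenomeSpec, simulate_genome

    L = 150_000
    m_start, m_end = 95_000, 107_000
    gspec = SimGenomeSpec(
        ploidy=2, chrom_lengths=[L], het_rate=0.005,
        repeat_spec=[RepeatSpec(18_000, [(0, 16_000), (0, 46_000)]),
                     RepeatSpec(m_end - m_start, [(0, m_start)])],
        seed=seed)
    genome = simulate_genome(gspec)
    h0, h1 = genome.haplotypes[0][0], genome.haplotypes[1][0]

    reads = []
    for hap, seq in ((0, h0), (1, h1)):
        for s in range(0, L - 6_000 + 1, 2_000):
            e = s + 6_000
            if s >= m_start and e <= m_end:
                continue  # corridor interior is covered only by design
            reads.append(SeqRecord(f"t{hap}_{s:06d}", seq[s:e]))
    spanner = SeqRecord("xspan_h0", h0[93_000:109_000])
    bridge = SeqRecord("bridge_m", h0[97_000:104_000])  # purely homozygous
    reads += [spanner, bridge]

    ul_reads = []
    for hap, seq in ((0, h0), (1, h1)):
        for s in range(0, L - 35_000 + 1, 10_000):
            ul_reads.append(SeqRecord(f"u{hap}_{s:06d}", seq[s : s + 35_000]))

    return ContainedRescueFixture(
        genome=genome, reads=reads, ul_reads=ul_reads,
        critical="bridge_m", spanner="xspan_h0",
        overlap_params=OverlapParams(k=21, min_ovlp=1500, max_div=0.0),
        align_params=ULAlignParams(),
    )


@dataclass
class IncorporationExample:
    unitig_graph: StringGraph
    iseqs: list            # IntegerSequence walks of the backbone
    residual_expected: set  # unitig ids expected to survive as residual nodes
    shared_unitig: int      # homozygous unitig expected to back two nodes
    haplotype_walks: list   # truth element walks per haplotype


def incorporation_example(seed: int = 0) -> IncorporationExample:
    rng = np.random.default_rng(seed)
    x1 = _rand_seq(rng, 5000)
    x2 = _rand_seq(rng, 5000)
    z = _rand_seq(rng, 7000)    # shared segment 1
    y1 = _rand_seq(rng, 5000)
    y2 = _rand_seq(rng, 5000)
    w = _rand_seq(rng, 6000)    # shared segment 2
    t = _rand_seq(rng, 2000)    # haplotype-1 tail beyond ultra-long reach
    g1 = x1 + z + y1 + w + t
    g2 = x2 + z + y2 + w

    seg1 = {1: (0, 5200), 3: (5000, 12000), 4: (11800, 17200),
            6: (17000, 23000), 7: (22800, 25000)}
    seg2 = {2: (0, 5200), 5: (11800, 17200)}
    ug = StringGraph()
    for uid, (s, e) in sorted(seg1.items()):
        ug.add_node(uid, seq=g1[s:e])
    for uid, (s, e) in sorted(seg2.items()):
        ug.add_node(uid, seq=g2[s:e])
    for a, b in [(1, 3), (2, 3), (3, 4), (3, 5), (4, 6), (5, 6), (6, 7)]:
        ug.add_edge(a, "+", b, "+", 200)

    iseqs = [
        IntegerSequence("ul_a", ((1, "+"), (3, "+"), (4, "+"))),
        IntegerSequence("ul_b", ((3, "+"), (4, "+"), (6, "+"))),
        IntegerSequence("ul_c", ((2, "+"), (3, "+"), (5, "+"))),
        IntegerSequence("ul_d", ((3, "+"), (5, "+"), (6, "+"))),
        IntegerSequence("ul_e", ((3, "+"), (4, "+"))),  # contained in ul_a/ul_b
        IntegerSequence("ul_f", ((6, "-"), (5, "-"))),  # contained (reverse) in ul_d
    ]
    return IncorporationExample(
        unitig_graph=ug,
        iseqs=iseqs,
        residual_expected={7},
        shared_unitig=6,
        haplotype_walks=[((1, "+"), (3, "+"), (4, "+"), (6, "+"), (7, "+")),
                         ((2, "+"), (3, "+"), (5, "+"), (6, "+"))],
    )
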