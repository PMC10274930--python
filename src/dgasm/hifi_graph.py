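"""Backbone string graph over accurate reads.

Reads become nodes and dovetail overlaps become bidirected edges. Contained
reads are (optionally) kept as flagged nodes wired by their own genuine
dovetail overlaps; with exact reads the transitive reduction then threads
them into chains, so an ultra-long alignment path can traverse them — the
prerequisite for contained-read rescue. Cleaning at this stage is
deliberately conservative (tips and unsupported parallel branches only):
ambiguous branch resolution is deferred to ultra-long edge support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Optional

from ._kmer import revcomp
from .errors import ConsistencyError
from .formats import SeqRecord
from .graph import Member, StringGraph, flip, maximal_chains
from .overlap import Overlap, classify_contained


@dataclass
class Unitig:
    """A maximal non-branching chain of reads, collapsed to one node."""

    id: int
    members: list[Member]
    seq: Optional[str]
    length: int

    @property
    def path(self) -> list[tuple[Hashable, str]]:
        return [(m.read_id, m.orient) for m in self.members]


def _arc_from_overlap(ov: Overlap, la: int, lb: int):
    """Translate a dovetail overlap into one arc statement (a,ao)->(b,bo)."""
    if ov.strand == "same":
        if ov.a_end == la and ov.b_start == 0:
            return (ov.a_id, "+", ov.b_id, "+")
        if ov.a_start == 0 and ov.b_end == lb:
            return (ov.b_id, "+", ov.a_id, "+")
    else:
        if ov.a_end == la and ov.b_end == lb:
            return (ov.a_id, "+", ov.b_id, "-")
        if ov.a_start == 0 and ov.b_start == 0:
            return (ov.b_id, "-", ov.a_id, "+")
    raise ConsistencyError(
        f"overlap {ov.a_id}/{ov.b_id} marked dovetail but reaches no read end")


def build_string_graph(reads: list[SeqRecord], overlaps: list[Overlap],
                       keep_contained: bool = True,
                       drop: Iterable = ()) -> StringGraph:
    """String graph from reads and their overlaps.

    With ``keep_contained`` contained reads become contained-flagged nodes;
    otherwise they are dropped before node creation (the classic string
    graph). ``drop`` removes further reads (e.g. rescue-rejected ones) before
    construction.
    """
    by_id = {r.id: r for r in reads}
    for ov in overlaps:
        if ov.a_id not in by_id or ov.b_id not in by_id:
            raise ConsistencyError(
                f"overlap references unknown read {ov.a_id!r}/{ov.b_id!r}")
    contained, _ = classify_contained(overlaps)
    excluded = set(drop)
    if not keep_contained:
        excluded |= contained
    g = StringGraph()
    for r in reads:
        if r.id in excluded:
            continue
        g.add_node(r.id, seq=r.seq, contained=r.id in contained)
    for ov in overlaps:
        if ov.kind != "dovetail":
            continue
        if ov.a_id in excluded or ov.b_id in excluded:
            continue
        a, ao, b, bo = _arc_from_overlap(ov, len(by_id[ov.a_id].seq),
                                         len(by_id[ov.b_id].seq))
        g.add_edge(a, ao, b, bo, ov.length)
    g.metadata["keep_contained"] = keep_contained
    return g


def transitive_reduction(graph: StringGraph, fuzz: int = 10) -> StringGraph:
    """Remove edges implied by a consistent two-edge path (Myers-style).

    An arc v->x is removed when some v->w->x exists with matching total
    extension within ``fuzz`` bp. The minimal-extension arc out of every node
    end is irreducible, so every removed edge remains realised by a surviving
    walk and node-end connectivity is preserved.
    """
    doomed: set[tuple] = set()
    for (v, vo) in sorted(graph._out, key=lambda t: (str(t[0]), t[1])):
        outs = graph.out_edges(v, vo)
        if len(outs) < 2:
            continue
        targets = {(w, wo): ov for w, wo, ov in outs}
        for w, wo, ov_vw in outs:
            ext_vw = graph.nodes[w].length - ov_vw
            for x, xo, ov_wx in graph.out_edges(w, wo):
                if x == v or (x, xo) == (w, wo) or (x, xo) not in targets:
                    continue
                ext_wx = graph.nodes[x].length - ov_wx
                ext_vx = graph.nodes[x].length - targets[(x, xo)]
                if abs(ext_vw + ext_wx - ext_vx) <= fuzz:
                    doomed.add((v, vo, x, xo))
    for v, vo, x, xo in sorted(doomed, key=lambda t: tuple(map(str, t))):
        if graph.has_edge(v, vo, x, xo):
            graph.remove_edge(v, vo, x, xo)
    return graph


def _chain_bp(graph: StringGraph, chain) -> int:
    total = graph.nodes[chain[0][0]].length
    for (a, ao), (b, bo) in zip(chain, chain[1:]):
        total += graph.nodes[b].length - graph.overlap_len(a, ao, b, bo)
    return total


def _is_tip(graph: StringGraph, chain) -> bool:
    first, last = chain[0], chain[-1]
    dead_left = graph.degree(first[0], flip(first[1])) == 0
    dead_right = graph.degree(last[0], last[1]) == 0
    return dead_left != dead_right  # exactly one dangling end


def clean_graph(graph: StringGraph, tip_len: int,
                min_edge_reads: int = 2) -> StringGraph:
    """Conservative cleaning: short dangling tips and unsupported parallel
    branches. Branches with >= ``min_edge_reads`` member reads are never cut
    here — heterozygous bubbles are phasing substrate, and competing edges at
    repeat junctions are left for ultra-long support to arbitrate.
    """
    for _ in range(5):
        changed = False
        for chain in maximal_chains(graph):
            if _is_tip(graph, chain) and _chain_bp(graph, chain) < tip_len:
                for nid, _o in chain:
                    graph.remove_node(nid)
                changed = True
        if not changed:
            break

    # pop parallel branches with too few supporting reads
    def walk(w, wo, limit=50):
        """Follow a branch until the first merge point; None if it branches."""
        interior = []
        cur = (w, wo)
        for _ in range(limit):
            if graph.degree(cur[0], flip(cur[1])) != 1:
                return interior, cur  # merge point (extra in-edges)
            outs = graph.out_edges(*cur)
            if len(outs) != 1:
                return None, None
            interior.append(cur)
            cur = (outs[0][0], outs[0][1])
        return None, None

    for (v, vo) in sorted(graph._out, key=lambda t: (str(t[0]), t[1])):
        outs = graph.out_edges(v, vo)
        if len(outs) != 2:
            continue
        sides = []
        for w, wo, _ov in sorted(outs, key=lambda t: (str(t[0]), t[1])):
            interior, end = walk(w, wo)
            sides.append((interior, end))
        (int1, end1), (int2, end2) = sides
        if end1 is None or end2 is None or end1 != end2:
            continue
        if {n for n, _ in int1} & {n for n, _ in int2}:
            continue
        small, big = (int1, int2) if len(int1) <= len(int2) else (int2, int1)
        if len(small) < min_edge_reads <= len(big):
            if small:
                for nid, _o in small:
                    graph.remove_node(nid)
            else:
                # direct shortcut edge parallel to a supported branch
                for w, wo, _ov in graph.out_edges(v, vo):
                    if (w, wo) == end1:
                        graph.remove_edge(v, vo, w, wo)
                        break
    return graph


def make_unitigs(graph: StringGraph) -> tuple[list[Unitig], StringGraph]:
    """Collapse maximal non-branching chains into unitigs.

    Returns the unitigs (integer ids starting at 1 — the alphabet of the
    integer space) and the unitig-level string graph whose nodes carry the
    member placements.
    """
    chains = sorted(maximal_chains(graph), key=lambda ch: str(ch[0][0]))
    unitigs: list[Unitig] = []
    entry: dict[tuple, tuple] = {}
    for i, chain in enumerate(chains, start=1):
        members: list[Member] = []
        seq_parts: list[str] = []
        start = 0
        prev = None
        for rid, orient in chain:
            node = graph.nodes[rid]
            if prev is not None:
                ov = graph.overlap_len(prev[0], prev[1], rid, orient)
                start = members[-1].end - ov
                if node.seq is not None:
                    oseq = node.seq if orient == "+" else revcomp(node.seq)
                    seq_parts.append(oseq[ov:])
            else:
                if node.seq is not None:
                    seq_parts.append(node.seq if orient == "+" else revcomp(node.seq))
            members.append(Member(rid, orient, start, start + node.length,
                                  node.contained))
            prev = (rid, orient)
        seq = "".join(seq_parts) if seq_parts and graph.nodes[chain[0][0]].seq else None
        length = members[-1].end
        unitigs.append(Unitig(i, members, seq, length))
        entry[(chain[0][0], chain[0][1])] = (i, "+")
        entry[(chain[-1][0], flip(chain[-1][1]))] = (i, "-")

    ug = StringGraph()
    for u in unitigs:
        ug.add_node(u.id, length=u.length, seq=u.seq, members=u.members)
    for u in unitigs:
        for uo, end in (("+", u.members[-1]), ("-", u.members[0])):
            rid = end.read_id
            ro = end.orient if uo == "+" else flip(end.orient)
            for t, to, ov in graph.out_edges(rid, ro):
                if (t, to) not in entry:
                    raise ConsistencyError(
                        f"arc from unitig {u.id} enters read {t!r} mid-unitig")
                v, vo = entry[(t, to)]
                ug.add_edge(u.id, uo, v, vo, ov)
    return unitigs, ug
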