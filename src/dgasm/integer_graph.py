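"""The second string graph, over integer-encoded ultra-long reads.

Sequences here are ordered lists of oriented unitig identifiers; overlaps are
exact suffix-prefix matches (or exact containment) in that alphabet, which
makes overlap detection cheap and noise-free — the graph alignment already
absorbed the base-level errors. Cleaning is deliberately aggressive:
ultra-long reads are long enough to walk through repetitive and homozygous
regions, so competing edges are resolved to the single best one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ConsistencyError
from .graph import StringGraph, flip, maximal_chains
from .ul_align import IntegerSequence


def reverse_iseq(elements: tuple) -> tuple:
    """Reverse the element order and flip every strand (an involution)."""
    return tuple((nid, flip(o)) for nid, o in reversed(elements))


@dataclass
class IntegerOverlap:
    a_id: str
    b_id: str
    strand: str        # 'same' | 'opposite': orientation of b relative to a
    length: int        # shared oriented elements
    kind: str          # 'dovetail' | 'a_contains_b' | 'b_contains_a'
    a_suffix: bool = True  # dovetail: suffix of a matches prefix of oriented b


@dataclass
class IntegerContig:
    id: str
    elements: tuple

    def __len__(self) -> int:
        return len(self.elements)


def _runs(hay: tuple, needle: tuple) -> bool:
    n, m = len(hay), len(needle)
    return any(hay[i : i + m] == needle for i in range(n - m + 1))


def _max_dovetail(a: tuple, b: tuple, min_iov: int) -> int:
    """Longest m >= min_iov with suffix(a, m) == prefix(b, m); 0 if none."""
    top = min(len(a), len(b))
    for m in range(top, min_iov - 1, -1):
        if a[-m:] == b[:m]:
            return m
    return 0


def integer_overlaps(iseqs: list[IntegerSequence], min_iov: int = 1
                     ) -> list[IntegerOverlap]:
    """All exact overlaps of length >= min_iov between any pair, either
    relative orientation. Containment (one sequence an exact oriented run of
    the other) shadows dovetails for that pair; equal sequences mark the
    later one contained.
    """
    by_elem: dict = {}
    for i, s in enumerate(iseqs):
        for nid, _o in s.elements:
            by_elem.setdefault(nid, set()).add(i)
    pairs = set()
    for ids in by_elem.values():
        ids = sorted(ids)
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                pairs.add((ids[x], ids[y]))

    out: list[IntegerOverlap] = []
    for i, j in sorted(pairs):
        a, b = iseqs[i].elements, iseqs[j].elements
        br = reverse_iseq(b)
        containment = None
        if len(b) <= len(a):
            if _runs(a, b):
                containment = ("same", len(b), "a_contains_b")
            elif _runs(a, br):
                containment = ("opposite", len(b), "a_contains_b")
        if containment is None and len(a) < len(b):
            if _runs(b, a):
                containment = ("same", len(a), "b_contains_a")
            elif _runs(br, a):
                containment = ("opposite", len(a), "b_contains_a")
        if containment is not None:
            strand, length, kind = containment
            out.append(IntegerOverlap(iseqs[i].ul_id, iseqs[j].ul_id,
                                      strand, length, kind))
            continue
        for strand, ob in (("same", b), ("opposite", br)):
            m = _max_dovetail(a, ob, min_iov)
            if m and m < min(len(a), len(ob)):
                out.append(IntegerOverlap(iseqs[i].ul_id, iseqs[j].ul_id,
                                          strand, m, "dovetail", True))
            m = _max_dovetail(ob, a, min_iov)
            if m and m < min(len(a), len(ob)):
                out.append(IntegerOverlap(iseqs[i].ul_id, iseqs[j].ul_id,
                                          strand, m, "dovetail", False))
    return out


def build_integer_graph(iseqs: list[IntegerSequence],
                        overlaps: list[IntegerOverlap]) -> StringGraph:
    """Integer string graph: contained sequences dropped unconditionally
    (an ultra-long read is unlikely to be a critical contained read), then
    exact transitive reduction (fuzz 0, measured in elements)."""
    from .hifi_graph import transitive_reduction

    by_id = {s.ul_id: s for s in iseqs}
    contained = set()
    for ov in overlaps:
        if ov.kind == "a_contains_b":
            contained.add(ov.b_id)
        elif ov.kind == "b_contains_a":
            contained.add(ov.a_id)
    g = StringGraph()
    for s in iseqs:
        if s.ul_id in contained:
            continue
        g.add_node(s.ul_id, length=len(s.elements), payload=s.elements)
    for ov in overlaps:
        if ov.kind != "dovetail":
            continue
        if ov.a_id in contained or ov.b_id in contained:
            continue
        if ov.a_id not in by_id or ov.b_id not in by_id:
            raise ConsistencyError("integer overlap references unknown sequence")
        bo = "+" if ov.strand == "same" else "-"
        if ov.a_suffix:
            g.add_edge(ov.a_id, "+", ov.b_id, bo, ov.length)
        else:
            g.add_edge(ov.b_id, bo, ov.a_id, "+", ov.length)
    transitive_reduction(g, fuzz=0)
    return g


def aggressive_clean(graph: StringGraph, tip_nodes: int = 2) -> StringGraph:
    """Keep only the best edge on every crowded node side (longest overlap,
    ties to the longer neighbour then the smaller id), drop short integer
    tips, iterate to a fixed point."""
    while True:
        changed = False
        losers: list = []
        for (v, vo) in sorted(graph._out, key=lambda t: (str(t[0]), t[1])):
            outs = graph.out_edges(v, vo)
            if len(outs) < 2:
                continue
            ranked = sorted(
                outs,
                key=lambda t: (-t[2], -graph.nodes[t[0]].length, str(t[0]), t[1]))
            for b, bo, _ov in ranked[1:]:
                graph.remove_edge(v, vo, b, bo)
                losers.append(b)
                changed = True
        # a node orphaned by the cuts is dangling noise, not a real contig
        if tip_nodes >= 1:
            for b in losers:
                if (b in graph.nodes and graph.degree(b, "+") == 0
                        and graph.degree(b, "-") == 0):
                    graph.remove_node(b)
        for chain in maximal_chains(graph):
            first, last = chain[0], chain[-1]
            dead_left = graph.degree(first[0], flip(first[1])) == 0
            dead_right = graph.degree(last[0], last[1]) == 0
            if (dead_left != dead_right) and len(chain) <= tip_nodes:
                for nid, _o in chain:
                    graph.remove_node(nid)
                changed = True
        if not changed:
            return graph


def integer_contigs(graph: StringGraph) -> list[IntegerContig]:
    """One contig per maximal non-branching path, spelled by concatenating
    member element lists beyond each overlap; emitted in canonical
    orientation (the lexicographically smaller of itself and its reverse)."""
    contigs = []
    for n, chain in enumerate(sorted(maximal_chains(graph),
                                     key=lambda ch: str(ch[0][0]))):
        first_id, first_o = chain[0]
        elems = list(graph.nodes[first_id].payload if first_o == "+"
                     else reverse_iseq(graph.nodes[first_id].payload))
        for (a, ao), (b, bo) in zip(chain, chain[1:]):
            if not graph.has_edge(a, ao, b, bo):
                raise ConsistencyError("chain step without a graph edge")
            ov = graph.overlap_len(a, ao, b, bo)
            nxt = (graph.nodes[b].payload if bo == "+"
                   else reverse_iseq(graph.nodes[b].payload))
            if tuple(elems[-ov:]) != tuple(nxt[:ov]):
                raise ConsistencyError("inconsistent overlap while spelling contig")
            elems.extend(nxt[ov:])
        elems = tuple(elems)
        canon = min((elems, reverse_iseq(elems)),
                    key=lambda e: tuple((str(n_), o_) for n_, o_ in e))
        contigs.append(IntegerContig(f"ic{n + 1}", canon))
    return contigs


def write_integer_contigs(contigs: Iterable[IntegerContig], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tn_elements\telements\n")
        for c in contigs:
            fh.write(f"{c.id}\t{len(c.elements)}\t"
                     + ",".join(f"{n}{o}" for n, o in c.elements) + "\n")
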