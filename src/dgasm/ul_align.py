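"""Ultra-long read alignment to the backbone graph.

Minimizer anchors are collected per graph node, clustered into per-node
linear segments on a fixed diagonal (the simulator is substitution-only, so
true segments are band-limited), and chained across graph edges by dynamic
programming with a gap-consistency penalty. The winning chain, projected to
its oriented node identifiers, is the read's integer sequence: base-level
detail is deliberately discarded, which is also what corrects the read — the
backbone nodes supply the accurate bases.

The same chains drive contained-read rescue (a contained read is critical
when enough ultra-long chains traverse the graph interval holding it) and
the edge support weights used for cleaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional

import numpy as np

from ._kmer import canonical_kmers, encode, minimizer_positions
from .errors import ConsistencyError
from .formats import PafRecord, SeqRecord
from .graph import StringGraph, edge_key


@dataclass
class ULAlignParams:
    k: int = 17
    w: int = 11
    min_anchors: int = 3       # anchors required per chain segment
    min_score: int = 5         # total anchors required to call a read aligned
    max_gap: int = 2000        # max gap-length inconsistency across an edge
    diag_band: int = 500       # diagonal clustering half-width
    max_occ: int = 500         # ignore minimizers more frequent than this
    ambiguity_ratio: float = 0.98  # trim chain ends tied this closely with a competing branch


@dataclass
class ChainSeg:
    """One linear alignment of a UL read to one oriented graph node."""

    node: Hashable
    strand: str
    ul_start: int
    ul_end: int
    n_start: int
    n_end: int
    count: int
    anchor_pos: np.ndarray = field(repr=False, default=None)


@dataclass
class ULAlignment:
    ul_id: str
    chain: list[ChainSeg]
    score: float

    @property
    def path(self) -> tuple:
        return tuple((s.node, s.strand) for s in self.chain)


@dataclass(frozen=True)
class IntegerSequence:
    ul_id: str
    elements: tuple  # ((node_id, '+'|'-'), ...)

    def __len__(self) -> int:
        return len(self.elements)


class GraphIndex:
    """Sorted canonical k-mer index over all node sequences of a graph."""

    def __init__(self, graph: StringGraph, k: int):
        self.k = k
        self.node_ids = sorted((n for n in graph.nodes
                                if graph.nodes[n].seq is not None), key=str)
        vals, nidx, pos, strand = [], [], [], []
        for i, nid in enumerate(self.node_ids):
            canon, st, valid = canonical_kmers(encode(graph.nodes[nid].seq), k)
            sel = np.nonzero(valid)[0]
            vals.append(canon[sel])
            nidx.append(np.full(sel.size, i, np.int32))
            pos.append(sel.astype(np.int64))
            strand.append(st[sel])
        if vals:
            v = np.concatenate(vals)
            order = np.argsort(v, kind="stable")
            self.vals = v[order]
            self.nidx = np.concatenate(nidx)[order]
            self.pos = np.concatenate(pos)[order]
            self.strand = np.concatenate(strand)[order]
        else:
            self.vals = np.empty(0, np.uint64)
            self.nidx = np.empty(0, np.int32)
            self.pos = np.empty(0, np.int64)
            self.strand = np.empty(0, np.uint8)
        self.lengths = {nid: graph.nodes[nid].length for nid in self.node_ids}


def _segments_for_read(read: SeqRecord, index: GraphIndex,
                       params: ULAlignParams) -> list[ChainSeg]:
    codes = encode(read.seq)
    canon, qstrand, valid = canonical_kmers(codes, params.k)
    mins = minimizer_positions(canon, valid, params.w)
    if mins.size == 0:
        return []
    qv, qs, qp = canon[mins], qstrand[mins], mins
    lo = np.searchsorted(index.vals, qv, "left")
    hi = np.searchsorted(index.vals, qv, "right")
    counts = hi - lo
    keep = (counts > 0) & (counts <= params.max_occ)
    if not keep.any():
        return []
    lo, hi, qs_k, qp_k = lo[keep], hi[keep], qs[keep], qp[keep]
    spans = (hi - lo).astype(np.int64)
    idx = np.concatenate([np.arange(l, h) for l, h in zip(lo.tolist(), hi.tolist())])
    node = index.nidx[idx]
    npos = index.pos[idx]
    nstr = index.strand[idx]
    qpos = np.repeat(qp_k, spans)
    rel = (np.repeat(qs_k, spans) ^ nstr).astype(np.int64)
    diag = np.where(rel == 0, qpos - npos, qpos + npos)

    order = np.lexsort((qpos, diag, rel, node))
    node, npos, qpos, rel, diag = (a[order] for a in (node, npos, qpos, rel, diag))
    brk = np.nonzero(
        (np.diff(node) != 0) | (np.diff(rel) != 0)
        | (np.abs(np.diff(diag)) > params.diag_band))[0] + 1
    bounds = np.concatenate(([0], brk, [node.size]))
    segs: list[ChainSeg] = []
    k = params.k
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e - s < params.min_anchors:
            continue
        nid = index.node_ids[int(node[s])]
        strand = "+" if rel[s] == 0 else "-"
        ap = np.sort(qpos[s:e])
        segs.append(ChainSeg(nid, strand,
                             int(ap[0]), int(ap[-1]) + k,
                             int(npos[s:e].min()), int(npos[s:e].max()) + k,
                             int(e - s), ap))
    segs.sort(key=lambda g: (g.ul_start, g.ul_end, str(g.node), g.strand))
    return segs


def _transition(si: ChainSeg, sj: ChainSeg, graph: StringGraph,
                params: ULAlignParams):
    """Gap inconsistency (bp) of chaining sj after si across a graph edge,
    or None when the transition is not allowed."""
    if not (si.ul_start < sj.ul_start and si.ul_end < sj.ul_end):
        return None
    if not graph.has_edge(si.node, si.strand, sj.node, sj.strand):
        return None
    ov = graph.overlap_len(si.node, si.strand, sj.node, sj.strand)
    li = graph.nodes[si.node].length
    lj = graph.nodes[sj.node].length
    exit_rem = li - si.n_end if si.strand == "+" else si.n_start
    entry_off = sj.n_start if sj.strand == "+" else lj - sj.n_end
    gapdiff = abs((sj.ul_start - entry_off) - (si.ul_end + exit_rem - ov))
    return gapdiff if gapdiff <= params.max_gap else None


def _trim_ambiguous_ends(chain: list[ChainSeg], segs: list[ChainSeg],
                         graph: StringGraph, params: ULAlignParams) -> list[ChainSeg]:
    """Drop terminal chain segments whose anchors are (nearly) matched by a
    competing extension at the same junction.

    Where two graph branches carry the same sequence near a junction (repeat
    overhangs absorbed into flanking nodes), a read whose flank ends inside
    that shared stretch cannot resolve the branch; committing to either arm
    would fabricate a walk. Such uninformative terminal segments are removed;
    reads with real flanking signal (the homologous haplotype arm differs by
    its SNV alleles) keep their exits.
    """
    ratio = params.ambiguity_ratio
    while len(chain) >= 2:
        last, prev = chain[-1], chain[-2]
        chosen = int(last.anchor_pos.size
                     - np.searchsorted(last.anchor_pos, prev.ul_end))
        best_alt = 0
        for s in segs:
            if s is last or (s.node, s.strand) == (last.node, last.strand):
                continue
            if _transition(prev, s, graph, params) is None:
                continue
            alt = int(s.anchor_pos.size - np.searchsorted(s.anchor_pos, prev.ul_end))
            best_alt = max(best_alt, alt)
        if chosen == 0 or best_alt >= ratio * chosen:
            chain.pop()
        else:
            break
    while len(chain) >= 2:
        first, nxt = chain[0], chain[1]
        chosen = int(np.searchsorted(first.anchor_pos, nxt.ul_start))
        best_alt = 0
        for s in segs:
            if s is first or (s.node, s.strand) == (first.node, first.strand):
                continue
            if _transition(s, nxt, graph, params) is None:
                continue
            alt = int(np.searchsorted(s.anchor_pos, nxt.ul_start))
            best_alt = max(best_alt, alt)
        if chosen == 0 or best_alt >= ratio * chosen:
            chain.pop(0)
        else:
            break
    return chain


def _chain_segments(segs: list[ChainSeg], graph: StringGraph,
                    params: ULAlignParams):
    """Best-scoring chain over the segment DAG (edges of the graph only).

    Score = 100 x newly-covered anchors - gap inconsistency in bp. Ties fall
    to fewer nodes, then larger total node length, then the lexicographically
    smallest path — a chain that skips a redundant contained node wins.
    """
    n = len(segs)
    score = [0] * n
    meta = []  # (-(nnodes), sumlen)
    pred = [-1] * n
    paths: list[tuple] = []
    for j in range(n):
        sj = segs[j]
        lj = graph.nodes[sj.node].length
        best = (100 * sj.count, -1, lj)
        bpred = -1
        bpath = ((str(sj.node), sj.strand),)
        for i in range(j):
            si = segs[i]
            gapdiff = _transition(si, sj, graph, params)
            if gapdiff is None:
                continue
            new = int(sj.anchor_pos.size
                      - np.searchsorted(sj.anchor_pos, si.ul_end))
            cand = (score[i] + 100 * new - gapdiff,
                    meta[i][0] - 1, meta[i][1] + lj)
            cpath = paths[i] + ((str(sj.node), sj.strand),)
            if cand > best or (cand == best and cpath < bpath):
                best, bpred, bpath = cand, i, cpath
        score[j] = best[0]
        meta.append((best[1], best[2]))
        pred[j] = bpred
        paths.append(bpath)
    if n == 0:
        return None, 0
    keys = [(score[j], meta[j][0], meta[j][1]) for j in range(n)]
    bestj = 0
    for j in range(1, n):
        if keys[j] > keys[bestj] or (keys[j] == keys[bestj]
                                     and paths[j] < paths[bestj]):
            bestj = j
    chain = []
    j = bestj
    while j != -1:
        chain.append(segs[j])
        j = pred[j]
    chain.reverse()
    chain = _trim_ambiguous_ends(chain, segs, graph, params)
    return chain, score[bestj]


def align_ul(ul_reads: list[SeqRecord], graph: StringGraph,
             params: ULAlignParams = ULAlignParams(),
             index: Optional[GraphIndex] = None
             ) -> tuple[list[ULAlignment], list[str]]:
    """Align every UL read to the graph; returns (alignments, unaligned ids)."""
    if index is None:
        index = GraphIndex(graph, params.k)
    alignments: list[ULAlignment] = []
    unaligned: list[str] = []
    for read in ul_reads:
        segs = _segments_for_read(read, index, params)
        chain, score = _chain_segments(segs, graph, params)
        total_anchors = sum(s.count for s in chain) if chain else 0
        if not chain or total_anchors < params.min_score:
            unaligned.append(read.id)
            continue
        alignments.append(ULAlignment(read.id, chain, score / 100.0))
    return alignments, unaligned


def encode_integer(alignments: Iterable[ULAlignment]) -> list[IntegerSequence]:
    """Project chains to oriented node identifiers, dropping empty chains."""
    out = []
    for aln in alignments:
        if aln.chain:
            out.append(IntegerSequence(aln.ul_id, aln.path))
    return out


def compute_edge_support(iseqs: Iterable[IntegerSequence],
                         graph: StringGraph) -> StringGraph:
    """ul_support(e) = number of distinct UL reads whose integer sequence
    contains e's oriented pair in either direction."""
    graph.reset_support()
    per_edge: dict[tuple, set] = {}
    for s in iseqs:
        for (a, ao), (b, bo) in zip(s.elements, s.elements[1:]):
            for nid in (a, b):
                if not graph.has_node(nid):
                    raise ConsistencyError(f"integer sequence references unknown node {nid!r}")
            if not graph.has_edge(a, ao, b, bo):
                raise ConsistencyError(
                    f"integer sequence {s.ul_id} uses missing edge {(a, ao, b, bo)}")
            per_edge.setdefault(edge_key(a, ao, b, bo), set()).add(s.ul_id)
    for (a, ao, b, bo), ids in per_edge.items():
        graph.set_support(a, ao, b, bo, len(ids))
    return graph


def rescue_contained(alignments: Iterable[ULAlignment], graph: StringGraph,
                     contained_ids: Iterable, min_rescue: int = 2,
                     pad: int = 50) -> tuple[set, set]:
    """Partition contained reads into {critical, removable}.

    A contained read is critical iff >= ``min_rescue`` distinct UL chains
    traverse a node interval containing its placement (own node, or its spot
    inside a unitig), with ``pad`` bp of slack for anchor edge effects.
    """
    contained_ids = set(contained_ids)
    placements: dict = {c: [] for c in contained_ids}
    for nid, node in graph.nodes.items():
        if nid in placements:
            placements[nid].append((nid, 0, node.length))
        if node.members:
            for m in node.members:
                if m.read_id in placements:
                    placements[m.read_id].append((nid, m.start, m.end))
    votes: dict = {c: set() for c in contained_ids}
    by_node: dict = {}
    for c, places in placements.items():
        for nid, s, e in places:
            by_node.setdefault(nid, []).append((c, s, e))
    for aln in alignments:
        for seg in aln.chain:
            for c, s, e in by_node.get(seg.node, ()):
                if seg.n_start <= s + pad and seg.n_end >= e - pad:
                    votes[c].add(aln.ul_id)
    critical = {c for c, v in votes.items() if len(v) >= min_rescue}
    return critical, contained_ids - critical


def essential_contained(overlaps, candidates: set, lengths: dict,
                        all_contained: set) -> set:
    """Junction-essentiality refinement of the coverage-based rescue.

    Among UL-covered candidate contained reads, keep only those whose removal
    would disconnect their overlap neighbourhood: starting from the graph of
    all non-removable reads, candidates are visited from shortest to longest
    and dropped whenever their dovetail partners remain mutually connected
    without them. What survives is the minimal bridge set — redundant
    contained reads threaded into chains by the reduction are let go, reads
    that patch a haplotype breakpoint stay.
    """
    removable_base = all_contained - candidates
    adj: dict = {}
    for ov in overlaps:
        if ov.kind != "dovetail":
            continue
        if ov.a_id in removable_base or ov.b_id in removable_base:
            continue
        adj.setdefault(ov.a_id, set()).add(ov.b_id)
        adj.setdefault(ov.b_id, set()).add(ov.a_id)
    critical = set()
    removed: set = set()
    for c in sorted(candidates, key=lambda r: (lengths.get(r, 0), str(r))):
        partners = {p for p in adj.get(c, ()) if p not in removed}
        if len(partners) <= 1:
            removed.add(c)
            continue
        start = next(iter(sorted(partners)))
        seen = {c, start}
        stack = [start]
        target = set(partners)
        target.discard(start)
        while stack and target:
            v = stack.pop()
            for nb in adj.get(v, ()):
                if nb in seen or nb in removed:
                    continue
                seen.add(nb)
                target.discard(nb)
                stack.append(nb)
        if target:
            critical.add(c)  # some partner unreachable without c
        else:
            removed.add(c)
    return critical


def weighted_clean(graph: StringGraph, min_support: int = 1) -> StringGraph:
    """UL-support-aware branch cleaning.

    At any node side with several edges: if at least one edge has support >=
    ``min_support``, cut all zero-support competitors; if none qualifies,
    fall back to keeping the longest-overlap edge(s). Supported competing
    edges are all kept — that ambiguity belongs to the integer graph.
    """
    for (v, vo) in sorted(graph._out, key=lambda t: (str(t[0]), t[1])):
        outs = graph.out_edges(v, vo)
        if len(outs) < 2:
            continue
        sups = {(b, bo): graph.get_support(v, vo, b, bo) for b, bo, _ in outs}
        if any(s >= min_support for s in sups.values()):
            for b, bo, _ov in outs:
                if sups[(b, bo)] == 0:
                    graph.remove_edge(v, vo, b, bo)
        else:
            best = max(ov for _b, _bo, ov in outs)
            for b, bo, ov in outs:
                if ov < best:
                    graph.remove_edge(v, vo, b, bo)
    return graph


def chains_to_paf(alignments: Iterable[ULAlignment], ul_reads: list[SeqRecord],
                  graph: StringGraph) -> list[PafRecord]:
    lens = {r.id: len(r.seq) for r in ul_reads}
    out = []
    for aln in alignments:
        for seg in aln.chain:
            out.append(PafRecord(
                aln.ul_id, lens[aln.ul_id], seg.ul_start, seg.ul_end,
                "+" if seg.strand == "+" else "-",
                str(seg.node), graph.nodes[seg.node].length,
                seg.n_start, seg.n_end, seg.count,
                max(seg.ul_end - seg.ul_start, seg.n_end - seg.n_start),
                255, {"cm": seg.count}))
    return out


def write_integer_seqs(iseqs: Iterable[IntegerSequence], path) -> None:
    with open(path, "w") as fh:
        fh.write("ul_id\telements\n")
        for s in iseqs:
            fh.write(s.ul_id + "\t" + ",".join(f"{n}{o}" for n, o in s.elements) + "\n")
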