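"""Final assembly graph and haplotype-resolved emission.

Incorporation removes from the backbone every unitig that appears on an
ultra-long integer contig, adds the contigs as nodes (spelled back to bases
by walking the backbone), and reconnects contig ends to whatever survived.
A unitig shared by several contigs legitimately backs several nodes.

Haplotype emission is graph-binning: nodes are labelled by haplotype-specific
k-mer markers; when one haplotype is emitted, every node dominated by another
haplotype's markers is discarded and the surviving maximal non-branching
paths are spelled out. The diploid case is the two-label special case of the
same rule, so polyploid emission needs no separate machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from ._kmer import canonical_kmer_set, count_in_set, revcomp
from .errors import ConsistencyError, ValidationError
from .formats import SeqRecord
from .graph import StringGraph, flip, maximal_chains
from .integer_graph import IntegerContig


def spell_sequence(elements: tuple, unitig_graph: StringGraph) -> str:
    """Base sequence of a walk of oriented unitigs (overlaps trimmed)."""
    first, fo = elements[0]
    node = unitig_graph.nodes.get(first)
    if node is None:
        raise ConsistencyError(f"walk references unknown unitig {first!r}")
    seq = node.seq if fo == "+" else revcomp(node.seq)
    parts = [seq]
    for (a, ao), (b, bo) in zip(elements, elements[1:]):
        if b not in unitig_graph.nodes:
            raise ConsistencyError(f"walk references unknown unitig {b!r}")
        if not unitig_graph.has_edge(a, ao, b, bo):
            raise ConsistencyError(f"walk step {(a, ao)}->{(b, bo)} has no edge")
        ov = unitig_graph.overlap_len(a, ao, b, bo)
        nseq = unitig_graph.nodes[b].seq
        parts.append((nseq if bo == "+" else revcomp(nseq))[ov:])
    return "".join(parts)


def incorporate(unitig_graph: StringGraph,
                contigs: Iterable[IntegerContig]) -> StringGraph:
    """Merge integer contigs into the backbone.

    Unitigs appearing in any contig leave the residual set; contig nodes are
    added with spelled sequences; boundary edges are reconstructed from the
    backbone edges at contig path ends (contig-contig and contig-residual).
    """
    contigs = list(contigs)
    used = set()
    for c in contigs:
        for nid, _o in c.elements:
            if nid not in unitig_graph.nodes:
                raise ConsistencyError(f"contig {c.id} references unknown unitig {nid!r}")
            used.add(nid)
    merged = StringGraph()
    for nid in sorted(set(unitig_graph.nodes) - used, key=str):
        n = unitig_graph.nodes[nid]
        merged.add_node(nid, length=n.length, seq=n.seq, members=n.members,
                        payload=((nid, "+"),), origin="residual")
    for c in contigs:
        seq = spell_sequence(c.elements, unitig_graph) \
            if unitig_graph.nodes[c.elements[0][0]].seq is not None else None
        length = seq and len(seq)
        if length is None:
            length = sum(unitig_graph.nodes[n].length for n, _ in c.elements)
        merged.add_node(c.id, length=length, seq=seq, payload=c.elements,
                        origin="contig")

    # entry points: which oriented merged node starts at oriented unitig (u, uo)
    starts: dict = {}
    for nid, node in merged.nodes.items():
        el = node.payload
        starts.setdefault(el[0], []).append((nid, "+"))
        rev_entry = (el[-1][0], flip(el[-1][1]))
        starts.setdefault(rev_entry, []).append((nid, "-"))

    for nid in sorted(merged.nodes, key=str):
        node = merged.nodes[nid]
        for mo in "+-":
            u, uo = (node.payload[-1] if mo == "+"
                     else (node.payload[0][0], flip(node.payload[0][1])))
            for v, vo, ov in unitig_graph.out_edges(u, uo):
                for tgt, to in starts.get((v, vo), ()):
                    merged.add_edge(nid, mo, tgt, to, ov)
    return merged


# ---------------------------------------------------------------------------
# markers and binning
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    label: str
    kmers: np.ndarray  # sorted canonical k-mers unique to this source
    k: int


@dataclass
class HaplotypeAssembly:
    label: str
    contigs: list  # SeqRecord
    provenance: list  # per contig: list of (node_id, orient, node_label or None)


def build_markers(hap_sources: list, k: int = 31,
                  labels: Optional[list] = None) -> list[MarkerSet]:
    """Marker set i = canonical k-mers present in source i and absent from all
    the others; sets are pairwise disjoint by construction."""
    if len(hap_sources) < 2:
        raise ValidationError("marker construction needs >= 2 sources")
    sets = [canonical_kmer_set(src, k) for src in hap_sources]
    if labels is None:
        labels = [f"hap{i + 1}" for i in range(len(sets))]
    out = []
    for i, s in enumerate(sets):
        others = [t for j, t in enumerate(sets) if j != i]
        mask = np.ones(s.size, bool)
        for t in others:
            idx = np.searchsorted(t, s)
            idx[idx == t.size] = max(t.size - 1, 0)
            if t.size:
                mask &= t[idx] != s
        out.append(MarkerSet(labels[i], s[mask], k))
    return out


def assign_markers(merged: StringGraph,
                   marker_sets: list[MarkerSet]) -> dict:
    """Per-node count vector of each haplotype's markers in the node sequence."""
    counts = {}
    for nid in sorted(merged.nodes, key=str):
        seq = merged.nodes[nid].seq
        if seq is None:
            counts[nid] = np.zeros(len(marker_sets), np.int64)
            continue
        counts[nid] = np.array(
            [count_in_set(seq, ms.kmers, ms.k) for ms in marker_sets], np.int64)
    return counts


def dominant_label(vec: np.ndarray, labels: list[str], min_markers: int = 2,
                   dom_ratio: float = 2.0) -> Optional[str]:
    order = np.argsort(vec)[::-1]
    c1, c2 = int(vec[order[0]]), int(vec[order[1]]) if vec.size > 1 else 0
    if c1 < min_markers:
        return None
    if c2 > 0 and c1 / c2 < dom_ratio:
        return None
    return labels[int(order[0])]


def graph_binning(merged: StringGraph, marker_counts: dict,
                  haplotype: str, marker_sets: list[MarkerSet],
                  min_markers: int = 2, dom_ratio: float = 2.0,
                  name_prefix: Optional[str] = None) -> HaplotypeAssembly:
    """Emit one haplotype: discard nodes dominated by any other haplotype's
    markers, keep unlabeled nodes, spell the surviving maximal paths."""
    labels = [ms.label for ms in marker_sets]
    if haplotype not in labels:
        raise ValidationError(f"unknown haplotype label {haplotype!r}")
    node_label = {nid: dominant_label(vec, labels, min_markers, dom_ratio)
                  for nid, vec in marker_counts.items()}
    sub = merged.copy()
    for nid, lab in node_label.items():
        if lab is not None and lab != haplotype:
            sub.remove_node(nid)
    prefix = name_prefix or haplotype
    contigs, provenance = [], []
    for n, chain in enumerate(sorted(maximal_chains(sub),
                                     key=lambda ch: str(ch[0][0])), start=1):
        first, fo = chain[0]
        seq = sub.nodes[first].seq
        seq = seq if fo == "+" else revcomp(seq)
        parts = [seq]
        for (a, ao), (b, bo) in zip(chain, chain[1:]):
            ov = sub.overlap_len(a, ao, b, bo)
            nseq = sub.nodes[b].seq
            parts.append((nseq if bo == "+" else revcomp(nseq))[ov:])
        contigs.append(SeqRecord(f"{prefix}_ctg{n:04d}", "".join(parts)))
        provenance.append([(nid, o, node_label.get(nid)) for nid, o in chain])
    return HaplotypeAssembly(haplotype, contigs, provenance)
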