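"""Ultra-long alignment, integer encoding, edge support, contained rescue."""

import numpy as np
import pytest

from dgasm import hifi_graph, ul_align
from dgasm._kmer import revcomp
from dgasm.errors import ConsistencyError
from dgasm.formats import SeqRecord
from dgasm.graph import StringGraph
from dgasm.overlap import OverlapParams, classify_contained, find_overlaps
from dgasm.simulate import parse_read_name
from dgasm.ul_align import (IntegerSequence, ULAlignParams, align_ul,
                            compute_edge_support, encode_integer,
                            essential_contained, rescue_contained,
                            weighted_clean)


def _path(aln):
    return tuple((n, o) for n, o in aln.path)


def test_exact_concatenation_chains_through_graph(toy, toy_graphs):
    by_id = {a.ul_id: a for a in toy_graphs["alignments"]}
    assert _path(by_id["u6"]) == (("h9", "+"), ("h10", "+"), ("h12", "+"), ("h6", "+"))
    assert _path(by_id["u7"]) == (("h10", "+"), ("h12", "+"), ("h6", "+"), ("h7", "+"))
    assert toy_graphs["unaligned"] == []


def test_reverse_complement_gives_reversed_chain(toy, toy_graphs):
    u6 = [r for r in toy.ul_reads if r.id == "u6"][0]
    flipped = SeqRecord("u6rc", revcomp(u6.seq))
    alns, _ = align_ul([flipped], toy_graphs["keep"], toy.align_params)
    assert _path(alns[0]) == (("h6", "-"), ("h12", "-"), ("h10", "-"), ("h9", "-"))


def test_chain_ul_spans_strictly_increase(toy_graphs):
    for aln in toy_graphs["alignments"]:
        starts = [s.ul_start for s in aln.chain]
        ends = [s.ul_end for s in aln.chain]
        assert starts == sorted(starts) and ends == sorted(ends)
        assert len(set(starts)) == len(starts)


def test_chains_match_truth_paths_on_simulation(small_diploid):
    genome = small_diploid["genome"]
    reads = small_diploid["hifi_records"]
    ovs = find_overlaps(reads, OverlapParams(21, 2_000, 0.0))
    g = hifi_graph.build_string_graph(reads, ovs, keep_contained=False)
    hifi_graph.transitive_reduction(g)
    hifi_graph.clean_graph(g, 24_000)
    unitigs, ug = hifi_graph.make_unitigs(g)
    # truth placement of each unitig (repeat-free: unique)
    placement = {}
    for u in unitigs:
        for hap in range(2):
            chrom = genome.haplotypes[hap][0]
            p = chrom.find(u.seq)
            if p >= 0:
                placement[u.id] = (hap, p, p + u.length, "+")
            else:
                p = chrom.find(revcomp(u.seq))
                if p >= 0:
                    placement[u.id] = (hap, p, p + u.length, "-")
    assert len(placement) == len(unitigs)

    alns, unaligned = align_ul(small_diploid["ul_records"], ug, ULAlignParams())
    assert not unaligned
    ok = 0
    for aln in alns:
        hap, chrom, start, end, strand = parse_read_name(aln.ul_id)
        truth = []
        for u in unitigs:
            uh, us, ue, uo = placement[u.id]
            if uh == hap and min(ue, end) - max(us, start) >= 250:
                truth.append((us, u.id, uo))
        truth.sort()
        tpath = tuple((uid, uo) for _s, uid, uo in truth)
        if strand == "-":
            tpath = tuple((uid, "+" if uo == "-" else "-") for uid, uo in reversed(tpath))
        got = _path(aln)
        # terminal elements shorter than 250 bp of read span are trimmed from
        # the comparison: below anchor resolution at junction overhangs
        if got in (tpath, tpath[1:], tpath[:-1], tpath[1:-1]):
            ok += 1
    assert ok / len(alns) >= 0.99


def test_encode_integer_is_projection(toy_graphs):
    iseqs = encode_integer(toy_graphs["alignments"])
    by_id = {s.ul_id: s for s in iseqs}
    assert by_id["u6"].elements == (("h9", "+"), ("h10", "+"), ("h12", "+"), ("h6", "+"))
    g = toy_graphs["keep"]
    for s in iseqs:
        for (a, ao), (b, bo) in zip(s.elements, s.elements[1:]):
            assert g.has_edge(a, ao, b, bo)


def test_unaligned_reads_absent_from_encoding():
    g = StringGraph()
    g.add_node(1, seq="ACGT" * 500)
    reads = [SeqRecord("junk", "TTTT" * 300)]
    alns, unaligned = align_ul(reads, g, ULAlignParams())
    assert unaligned == ["junk"] and encode_integer(alns) == []


def test_edge_support_toy_value(toy, toy_graphs):
    g = toy_graphs["keep"]
    iseqs = encode_integer(toy_graphs["alignments"])
    compute_edge_support(iseqs, g)
    a, b = toy.support_edge
    assert g.get_support(a, "+", b, "+") == 2  # u4 and u5 cross this junction
    assert g.get_support("h10", "+", "h12", "+") == 2  # u6 and u7


def test_edge_support_doubles_with_duplicated_reads(toy, toy_graphs):
    g = toy_graphs["keep"]
    iseqs = encode_integer(toy_graphs["alignments"])
    doubled = iseqs + [IntegerSequence(s.ul_id + "_dup", s.elements) for s in iseqs]
    compute_edge_support(iseqs, g)
    single = {(str(a), ao, str(b), bo): g.get_support(a, ao, b, bo)
              for a, ao, b, bo, _ in g.edges()}
    compute_edge_support(doubled, g)
    for (a, ao, b, bo, _) in g.edges():
        assert g.get_support(a, ao, b, bo) == 2 * single[(str(a), ao, str(b), bo)]


def test_edge_support_no_reads_all_zero(toy_graphs):
    g = toy_graphs["keep"]
    compute_edge_support([], g)
    assert all(g.get_support(a, ao, b, bo) == 0 for a, ao, b, bo, _ in g.edges())


def test_edge_support_unknown_node_rejected(toy_graphs):
    bad = [IntegerSequence("x", (("nope", "+"), ("h5", "+")))]
    with pytest.raises(ConsistencyError):
        compute_edge_support(bad, toy_graphs["keep"])


def test_rescue_toy_h12_critical_h11_removable(toy, toy_graphs):
    critical, removable = rescue_contained(
        toy_graphs["alignments"], toy_graphs["keep"], toy_graphs["contained"],
        min_rescue=2)
    assert critical == {"h12"} and removable == {"h11"}


def test_rescue_without_ul_everything_removable(toy_graphs):
    critical, removable = rescue_contained(
        [], toy_graphs["keep"], toy_graphs["contained"], min_rescue=2)
    assert critical == set() and removable == {"h11", "h12"}


def test_rescue_min_rescue_one_keeps_any_traversed_read(toy, toy_graphs):
    critical, _ = rescue_contained(
        toy_graphs["alignments"], toy_graphs["keep"], toy_graphs["contained"],
        min_rescue=1)
    assert "h12" in critical and "h11" not in critical


def test_strand_symmetry_of_alignment_and_support(toy, toy_graphs):
    g = toy_graphs["keep"]
    flipped = [SeqRecord(r.id, revcomp(r.seq)) for r in toy.ul_reads]
    alns, _ = align_ul(flipped, g, toy.align_params)
    compute_edge_support(encode_integer(alns), g)
    assert g.get_support("h5", "+", "h8", "+") == 2
    assert g.get_support("h10", "+", "h12", "+") == 2


# ---------------------------------------------------------------------------
# weighted cleaning
# ---------------------------------------------------------------------------

def _branch_graph(supports, olaps=(500, 400)):
    g = StringGraph()
    g.add_node("v", length=2000)
    g.add_node("a", length=2000)
    g.add_node("b", length=2000)
    g.add_edge("v", "+", "a", "+", olaps[0])
    g.add_edge("v", "+", "b", "+", olaps[1])
    g.set_support("v", "+", "a", "+", supports[0])
    g.set_support("v", "+", "b", "+", supports[1])
    return g


def test_weighted_clean_cuts_unsupported_competitor():
    g = _branch_graph((2, 0))
    weighted_clean(g, min_support=1)
    assert g.has_edge("v", "+", "a", "+") and not g.has_edge("v", "+", "b", "+")


def test_weighted_clean_falls_back_to_longest_overlap():
    g = _branch_graph((0, 0), olaps=(300, 450))
    weighted_clean(g, min_support=1)
    assert not g.has_edge("v", "+", "a", "+") and g.has_edge("v", "+", "b", "+")


def test_weighted_clean_keeps_competing_supported_edges():
    g = _branch_graph((2, 3))
    weighted_clean(g, min_support=1)
    assert g.has_edge("v", "+", "a", "+") and g.has_edge("v", "+", "b", "+")


# ---------------------------------------------------------------------------
# junction essentiality on the tiled fixture
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def rescue_fixture():
    from dgasm.examples import contained_rescue_fixture
    fx = contained_rescue_fixture(seed=0)
    ovs = find_overlaps(fx.reads, fx.overlap_params)
    contained, _ = classify_contained(ovs)
    g0 = hifi_graph.build_string_graph(fx.reads, ovs, keep_contained=True)
    hifi_graph.transitive_reduction(g0)
    _u, ug0 = hifi_graph.make_unitigs(g0)
    alns, _ = align_ul(fx.ul_reads, ug0, fx.align_params)
    return fx, ovs, contained, alns, ug0


def test_essential_contained_keeps_only_the_bridge(rescue_fixture):
    fx, ovs, contained, alns, ug0 = rescue_fixture
    covered, _ = rescue_contained(alns, ug0, contained, min_rescue=2)
    assert fx.critical in covered
    lengths = {r.id: len(r.seq) for r in fx.reads}
    critical = essential_contained(ovs, covered, lengths, contained)
    assert critical == {fx.critical}
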