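"""Graph incorporation, sequence spelling, markers and graph binning."""

import numpy as np
import pytest

from dgasm import integer_graph, merge_phase
from dgasm._kmer import revcomp
from dgasm.errors import ConsistencyError, ValidationError
from dgasm.formats import SeqRecord
from dgasm.graph import StringGraph
from dgasm.integer_graph import IntegerContig
from dgasm.merge_phase import (assign_markers, build_markers, graph_binning,
                               incorporate, spell_sequence)

rng = np.random.default_rng(55)
_B = np.frombuffer(b"ACGT", np.uint8)


def _rand(n):
    return _B[rng.integers(0, 4, n)].tobytes().decode()


@pytest.fixture(scope="module")
def merged(incorporation):
    seqs = incorporation.iseqs
    ig = integer_graph.build_integer_graph(
        seqs, integer_graph.integer_overlaps(seqs, 1))
    integer_graph.aggressive_clean(ig)
    contigs = integer_graph.integer_contigs(ig)
    return incorporate(incorporation.unitig_graph, contigs), contigs


def test_single_residual_unitig_after_incorporation(incorporation, merged):
    m, _ = merged
    residual = {n for n, node in m.nodes.items() if node.origin == "residual"}
    assert residual == incorporation.residual_expected
    assert all(node.origin == "contig" for n, node in m.nodes.items()
               if n not in residual)


def test_shared_unitig_backs_multiple_nodes(incorporation, merged):
    m, _ = merged
    backed = [n for n, node in m.nodes.items()
              if node.origin == "contig"
              and any(e == incorporation.shared_unitig for e, _o in node.payload)]
    assert len(backed) == 2


def test_boundary_edges_reconstructed(incorporation, merged):
    m, _ = merged
    (residual,) = incorporation.residual_expected
    partners = set()
    for o in "+-":
        for b, _bo, _ov in m.out_edges(residual, o):
            partners.add(b)
    assert len(partners) == 2  # both contigs reconnect to the leftover unitig


def test_empty_contigs_is_isomorphic_to_backbone(incorporation):
    ug = incorporation.unitig_graph
    m = incorporate(ug, [])
    assert set(m.nodes) == set(ug.nodes)
    assert all(n.origin == "residual" for n in m.nodes.values())
    assert {(str(a), ao, str(b), bo, ov) for a, ao, b, bo, ov in m.edges()} == \
           {(str(a), ao, str(b), bo, ov) for a, ao, b, bo, ov in ug.edges()}


def test_contig_referencing_unknown_unitig_rejected(incorporation):
    with pytest.raises(ConsistencyError):
        incorporate(incorporation.unitig_graph,
                    [IntegerContig("bad", ((999, "+"),))])


# ---------------------------------------------------------------------------
# spelling
# ---------------------------------------------------------------------------

def _mini_backbone():
    g = StringGraph()
    whole = _rand(1700)
    g.add_node(1, seq=whole[:1000])
    g.add_node(2, seq=whole[900:1700])
    g.add_edge(1, "+", 2, "+", 100)
    return g, whole


def test_spell_single_element():
    g, _ = _mini_backbone()
    assert spell_sequence(((1, "+"),), g) == g.nodes[1].seq
    assert spell_sequence(((1, "-"),), g) == revcomp(g.nodes[1].seq)


def test_spell_concatenation_arithmetic():
    g, whole = _mini_backbone()
    seq = spell_sequence(((1, "+"), (2, "+")), g)
    assert len(seq) == 1000 + 800 - 100
    assert seq == whole


def test_spell_missing_edge_rejected():
    g, _ = _mini_backbone()
    with pytest.raises(ConsistencyError):
        spell_sequence(((2, "+"), (1, "+")), g)


def test_spelled_contigs_are_truth_substrings(incorporation, merged):
    m, _ = merged
    ex = incorporation
    g1 = spell_sequence(ex.haplotype_walks[0], ex.unitig_graph)
    g2 = spell_sequence(ex.haplotype_walks[1], ex.unitig_graph)
    for node in m.nodes.values():
        if node.origin != "contig":
            continue
        assert (node.seq in g1 or node.seq in g2
                or revcomp(node.seq) in g1 or revcomp(node.seq) in g2)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def test_identical_sources_have_empty_marker_sets():
    src = _rand(5_000)
    sets = build_markers([src, src], k=31)
    assert all(ms.kmers.size == 0 for ms in sets)


def test_single_snv_yields_at_most_k_markers_each():
    src1 = _rand(3_000)
    pos = 1_500
    alt = "A" if src1[pos] != "A" else "C"
    src2 = src1[:pos] + alt + src1[pos + 1:]
    sets = build_markers([src1, src2], k=31)
    for ms in sets:
        assert 1 <= ms.kmers.size <= 31


def test_marker_sets_pairwise_disjoint():
    sources = [_rand(4_000) for _ in range(4)]
    sets = build_markers(sources, k=31)
    for i in range(4):
        for j in range(i + 1, 4):
            assert not np.intersect1d(sets[i].kmers, sets[j].kmers).size


def test_fewer_than_two_sources_rejected():
    with pytest.raises(ValidationError):
        build_markers([_rand(1_000)], k=31)


def test_assign_markers_counts():
    shared = _rand(2_000)
    uniq1, uniq2 = _rand(2_000), _rand(2_000)
    sets = build_markers([shared + uniq1, shared + uniq2], k=31)
    g = StringGraph()
    g.add_node("hom", seq=shared)
    g.add_node("het1", seq=uniq1)
    counts = assign_markers(g, sets)
    assert counts["hom"].tolist() == [0, 0]
    assert counts["het1"][0] > 0 and counts["het1"][1] == 0


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _binning_setup():
    hap1 = _rand(6_000)
    # haplotype 2: same as hap1 with a dense SNV block in the middle third
    mid = list(hap1[2_000:4_000])
    for i in range(0, len(mid), 40):
        mid[i] = "ACGT"[("ACGT".index(mid[i]) + 1) % 4]
    hap2 = hap1[:2_000] + "".join(mid) + hap1[4_000:]
    sets = build_markers([hap1, hap2], k=31)
    g = StringGraph()
    g.add_node("n1", seq=hap1[:2_500], origin="contig", payload=((1, "+"),))
    g.add_node("n2", seq=hap2[1_800:4_200], origin="contig", payload=((2, "+"),))
    g.add_node("hom", seq=hap1[4_500:6_000], origin="residual", payload=((3, "+"),))
    counts = assign_markers(g, sets)
    return g, sets, counts


def test_binning_discards_other_haplotype_nodes():
    g, sets, counts = _binning_setup()
    asm1 = graph_binning(g, counts, "hap1", sets)
    nodes1 = {n for path in asm1.provenance for n, _o, _l in path}
    assert "n2" not in nodes1 and "hom" in nodes1


def test_unlabeled_nodes_emitted_in_every_haplotype():
    g, sets, counts = _binning_setup()
    for hap in ("hap1", "hap2"):
        asm = graph_binning(g, counts, hap, sets)
        nodes = {n for path in asm.provenance for n, _o, _l in path}
        assert "hom" in nodes


def test_homozygous_graph_emissions_identical():
    seq = _rand(5_000)
    sets = build_markers([seq, seq], k=31)
    g = StringGraph()
    g.add_node("a", seq=seq[:3_000], payload=((1, "+"),), origin="contig")
    counts = assign_markers(g, sets)
    e1 = graph_binning(g, counts, "hap1", sets)
    e2 = graph_binning(g, counts, "hap2", sets)
    assert [c.seq for c in e1.contigs] == [c.seq for c in e2.contigs]


def test_unknown_haplotype_label_rejected():
    g, sets, counts = _binning_setup()
    with pytest.raises(ValidationError):
        graph_binning(g, counts, "hap9", sets)
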