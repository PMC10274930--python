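"""Backbone string graph: construction, reduction, cleaning, unitigs."""

import numpy as np
import pytest

from dgasm import hifi_graph
from dgasm.errors import ConsistencyError
from dgasm.formats import SeqRecord
from dgasm.graph import StringGraph, flip
from dgasm.hifi_graph import (build_string_graph, clean_graph, make_unitigs,
                              transitive_reduction)
from dgasm.overlap import Overlap, OverlapParams, find_overlaps
from dgasm.simulate import SimGenomeSpec, SimReadSpec, records, simulate_genome, simulate_reads
from oracles import check_reduction

rng = np.random.default_rng(31)
_B = np.frombuffer(b"ACGT", np.uint8)


def _rand(n):
    return _B[rng.integers(0, 4, n)].tobytes().decode()


def _tiling_reads(genome_len=3000, n=3, read_len=1400):
    g = _rand(genome_len)
    step = (genome_len - read_len) // (n - 1)
    return [SeqRecord(f"r{i}", g[i * step : i * step + read_len]) for i in range(n)]


def test_three_tiling_reads_three_nodes_two_edges():
    reads = _tiling_reads()
    ovs = find_overlaps(reads, OverlapParams(15, 200, 0.0))
    g = build_string_graph(reads, ovs)
    assert len(g.nodes) == 3 and g.n_edges() == 2


def test_overlap_with_unknown_read_rejected():
    reads = _tiling_reads()
    ovs = find_overlaps(reads, OverlapParams(15, 200, 0.0))
    ghost = Overlap("r0", "nope", "same", 0, 300, 0, 300, "dovetail", 1.0)
    with pytest.raises(ConsistencyError):
        build_string_graph(reads, ovs + [ghost])


def test_toy_contained_dropped_breaks_second_haplotype(toy, toy_graphs):
    g = toy_graphs["drop"]
    assert "h11" not in g.nodes and "h12" not in g.nodes
    comps = {frozenset(c) for c in g.components()}
    assert frozenset({"h9", "h10"}) in comps  # haplotype-2 entry severed
    assert frozenset({"h6", "h7"}) in comps


def test_toy_contained_kept_as_flagged_nodes(toy_graphs):
    g = toy_graphs["keep"]
    assert g.nodes["h11"].contained and g.nodes["h12"].contained
    assert not g.nodes["h3"].contained


def test_bidirected_edge_consistency(toy_graphs):
    g = toy_graphs["keep"]
    for a, ao, b, bo, ov in g.edges():
        assert g.has_edge(a, ao, b, bo)
        assert g.has_edge(b, flip(bo), a, flip(ao))
        assert g.overlap_len(b, flip(bo), a, flip(ao)) == ov


# ---------------------------------------------------------------------------
# transitive reduction
# ---------------------------------------------------------------------------

def _chain_graph():
    g = StringGraph()
    for nid, ln in (("a", 1000), ("b", 1000), ("c", 1000)):
        g.add_node(nid, length=ln)
    g.add_edge("a", "+", "b", "+", 600)
    g.add_edge("b", "+", "c", "+", 600)
    g.add_edge("a", "+", "c", "+", 200)  # ext 800 = 400 + 400
    return g


def test_textbook_reduction_removes_shortcut():
    g = _chain_graph()
    transitive_reduction(g, fuzz=10)
    assert not g.has_edge("a", "+", "c", "+")
    assert g.has_edge("a", "+", "b", "+") and g.has_edge("b", "+", "c", "+")


def test_reduction_is_fixed_point_on_irreducible_graph():
    g = _chain_graph()
    transitive_reduction(g, fuzz=10)
    before = set(g.edges())
    transitive_reduction(g, fuzz=10)
    assert set(g.edges()) == before


def test_inconsistent_shortcut_survives():
    g = _chain_graph()
    g.remove_edge("a", "+", "c", "+")
    g.add_edge("a", "+", "c", "+", 500)  # ext 500, not 800: length-inconsistent
    transitive_reduction(g, fuzz=10)
    assert g.has_edge("a", "+", "c", "+")


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_reduction_against_path_oracle(seed):
    r = np.random.default_rng(seed)
    glen = int(r.integers(5_000, 9_000))
    g = _B[r.integers(0, 4, glen)].tobytes().decode()
    reads, pos, i = [], 0, 0
    while pos < glen - 700:
        L = min(int(r.integers(500, 1200)), glen - pos)
        reads.append(SeqRecord(f"r{i}", g[pos : pos + L]))
        pos += int(r.integers(100, 400))
        i += 1
    ovs = find_overlaps(reads, OverlapParams(15, 100, 0.0))
    before = build_string_graph(reads, ovs, keep_contained=False)
    after = before.copy()
    transitive_reduction(after, fuzz=10)
    check_reduction(before, after, fuzz=10)


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _long_chain(g, ids, length=2000, olap=500):
    for nid in ids:
        g.add_node(nid, length=length)
    for a, b in zip(ids, ids[1:]):
        g.add_edge(a, "+", b, "+", olap)


def test_short_spur_removed():
    g = StringGraph()
    _long_chain(g, ["c1", "c2", "c3", "c4"])
    g.add_node("spur", length=300)
    g.add_edge("c2", "+", "spur", "+", 100)
    clean_graph(g, tip_len=1000)
    assert "spur" not in g.nodes and "c2" in g.nodes


def test_clean_is_identity_on_linear_chain():
    g = StringGraph()
    _long_chain(g, ["c1", "c2", "c3", "c4"])
    edges = set(g.edges())
    clean_graph(g, tip_len=1000)
    assert set(g.edges()) == edges


def test_heterozygous_bubble_retained():
    g = StringGraph()
    _long_chain(g, ["pre1", "pre2"])
    _long_chain(g, ["post1", "post2"])
    for branch in ("x", "y"):
        for n in (f"{branch}1", f"{branch}2"):
            g.add_node(n, length=2000)
        g.add_edge("pre2", "+", f"{branch}1", "+", 500)
        g.add_edge(f"{branch}1", "+", f"{branch}2", "+", 500)
        g.add_edge(f"{branch}2", "+", "post1", "+", 500)
    clean_graph(g, tip_len=1000, min_edge_reads=2)
    for n in ("x1", "x2", "y1", "y2"):
        assert n in g.nodes  # both haplotype branches survive


def test_single_read_artifact_branch_popped():
    g = StringGraph()
    _long_chain(g, ["pre1", "pre2"])
    _long_chain(g, ["post1", "post2"])
    for n in ("x1", "x2", "x3"):
        g.add_node(n, length=2000)
    g.add_edge("pre2", "+", "x1", "+", 500)
    g.add_edge("x1", "+", "x2", "+", 500)
    g.add_edge("x2", "+", "x3", "+", 500)
    g.add_edge("x3", "+", "post1", "+", 500)
    g.add_node("err", length=2000)
    g.add_edge("pre2", "+", "err", "+", 500)
    g.add_edge("err", "+", "post1", "+", 500)
    clean_graph(g, tip_len=100, min_edge_reads=2)
    assert "err" not in g.nodes
    assert all(n in g.nodes for n in ("x1", "x2", "x3"))


# ---------------------------------------------------------------------------
# unitigs
# ---------------------------------------------------------------------------

def test_linear_chain_collapses_to_one_unitig():
    reads = _tiling_reads(genome_len=5000, n=5, read_len=1400)
    ovs = find_overlaps(reads, OverlapParams(15, 200, 0.0))
    g = build_string_graph(reads, ovs, keep_contained=False)
    transitive_reduction(g)
    unitigs, ug = make_unitigs(g)
    assert len(unitigs) == 1 and ug.n_edges() == 0
    assert unitigs[0].length == 5000
    # spelled sequence reconstructs the sampled genome region
    first = reads[0].seq
    assert unitigs[0].seq[: len(first)] in (first,) or \
        unitigs[0].seq[-len(first):] == first


def test_perfect_bubble_gives_four_unitigs_four_edges():
    g = StringGraph()
    for nid in ("a1", "a2", "x", "y", "b1", "b2"):
        g.add_node(nid, length=2000)
    g.add_edge("a1", "+", "a2", "+", 500)
    g.add_edge("a2", "+", "x", "+", 500)
    g.add_edge("a2", "+", "y", "+", 500)
    g.add_edge("x", "+", "b1", "+", 500)
    g.add_edge("y", "+", "b1", "+", 500)
    g.add_edge("b1", "+", "b2", "+", 500)
    unitigs, ug = make_unitigs(g)
    assert len(unitigs) == 4 and ug.n_edges() == 4


def test_haploid_repeat_free_genome_one_unitig_per_chromosome():
    genome = simulate_genome(SimGenomeSpec(
        ploidy=1, chrom_lengths=[50_000, 30_000], het_rate=0.0, seed=41))
    reads = records(simulate_reads(genome, SimReadSpec(
        "accurate", 6_000, 1_500, 2_500, 12.0, seed=42)))
    ovs = find_overlaps(reads, OverlapParams(21, 1_500, 0.0))
    g = build_string_graph(reads, ovs, keep_contained=False)
    transitive_reduction(g)
    clean_graph(g, tip_len=18_000)
    unitigs, ug = make_unitigs(g)
    assert len(unitigs) == 2
    total = sum(u.length for u in unitigs)
    assert abs(total - 80_000) < 2 * 6_000  # within read-length edge losses
    for u in unitigs:
        hap = genome.haplotypes[0]
        from dgasm._kmer import revcomp
        assert any(u.seq in c or revcomp(u.seq) in c for c in hap)
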