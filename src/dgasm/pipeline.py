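"""End-to-end pipeline driver.

Stages: simulate (or load) -> accurate-read overlaps -> backbone string graph
(contained reads kept) -> ultra-long alignment -> contained-read rescue ->
rebuilt backbone -> integer encoding + edge support -> support-weighted
cleaning -> integer graph -> integer contigs -> incorporation -> marker
binning -> per-haplotype FASTA + metrics. ``hifi_only`` skips every
ultra-long stage (the accurate-read-only baseline); the run is deterministic
given the config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import evaluate, hifi_graph, integer_graph, merge_phase, simulate, ul_align
from .formats import SeqRecord, write_gfa, write_paf, write_seqs
from .overlap import OverlapParams, classify_contained, find_overlaps, overlaps_to_paf
from .simulate import RepeatSpec, SimGenomeSpec, SimReadSpec
from .ul_align import ULAlignParams

log = logging.getLogger("dgasm")


@dataclass
class PipelineConfig:
    seed: int = 0
    genome: SimGenomeSpec = field(default_factory=SimGenomeSpec)
    hifi: SimReadSpec = field(default_factory=lambda: SimReadSpec(
        "accurate", 6000, 2500, 1500, 10.0))
    ul: Optional[SimReadSpec] = field(default_factory=lambda: SimReadSpec(
        "ultralong", 35000, 8000, 18000, 14.0))
    overlap: OverlapParams = field(default_factory=lambda: OverlapParams(
        21, 1500, 0.0))
    ul_align: ULAlignParams = field(default_factory=ULAlignParams)
    fuzz: int = 10
    tip_len: Optional[int] = None  # default: 3x accurate mean read length
    min_edge_reads: int = 2
    min_rescue: int = 2
    min_support: int = 1
    min_iov: int = 1
    tip_nodes: int = 2
    marker_k: int = 31
    min_markers: int = 2
    dom_ratio: float = 2.0
    eval_min_len: int = 5000
    eval_mode: str = "exact"
    hifi_only: bool = False
    dump_stages: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        seed = int(d.pop("seed", 0))
        gd = d.pop("genome", {})
        reps = [RepeatSpec(r["unit_len"], [tuple(x) for x in r["loci"]],
                           r.get("divergence", 0.0))
                for r in gd.pop("repeats", [])]
        genome = SimGenomeSpec(seed=seed, repeat_spec=reps, **gd)
        hifi = SimReadSpec(role="accurate", seed=seed + 1, **d.pop("hifi"))
        uld = d.pop("ul", None)
        ul = SimReadSpec(role="ultralong", seed=seed + 2, **uld) if uld else None
        ovl = OverlapParams(**d.pop("overlap", {}))
        ula = ULAlignParams(**d.pop("ul_align", {}))
        return cls(seed=seed, genome=genome, hifi=hifi, ul=ul, overlap=ovl,
                   ul_align=ula, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _genome_records(genome) -> list[SeqRecord]:
    return [SeqRecord(f"hap{h}_chr{c}", seq)
            for h in range(genome.ploidy)
            for c, seq in enumerate(genome.haplotypes[h])]


def run_pipeline(cfg: PipelineConfig, outdir, hifi_only: Optional[bool] = None,
                 dump_stages: Optional[bool] = None) -> dict:
    """Run all stages; returns artifacts (objects and written paths)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hifi_only = cfg.hifi_only if hifi_only is None else hifi_only
    dump_stages = cfg.dump_stages if dump_stages is None else dump_stages

    genome = simulate.simulate_genome(cfg.genome)
    write_seqs(_genome_records(genome), outdir / "genome.fasta")
    simulate.write_snv_table(genome, outdir / "truth_snvs.tsv")
    hifi_truth = simulate.simulate_reads(genome, cfg.hifi)
    hifi_reads = simulate.records(hifi_truth)
    write_seqs(hifi_reads, outdir / "hifi.fastq", format="fastq")
    simulate.write_truth_table(hifi_truth, outdir / "hifi_truth.tsv")
    log.info("simulate: ploidy=%d genome=%dbp hifi_reads=%d",
             genome.ploidy, genome.haplotype_size(0), len(hifi_reads))

    ul_truth = []
    ul_reads: list[SeqRecord] = []
    if cfg.ul is not None and not hifi_only:
        ul_truth = simulate.simulate_reads(genome, cfg.ul)
        ul_reads = simulate.records(ul_truth)
        write_seqs(ul_reads, outdir / "ul.fastq", format="fastq")
        simulate.write_truth_table(ul_truth, outdir / "ul_truth.tsv")
        log.info("simulate: ul_reads=%d", len(ul_reads))

    overlaps = find_overlaps(hifi_reads, cfg.overlap)
    write_paf(overlaps_to_paf(overlaps, hifi_reads), outdir / "overlaps.paf")
    contained, _ = classify_contained(overlaps)
    log.info("overlap: %d overlaps, %d contained reads", len(overlaps), len(contained))

    tip_len = cfg.tip_len or 3 * cfg.hifi.mean_len
    result: dict = {"genome": genome, "outdir": outdir}

    def _dump(graph, name):
        if dump_stages:
            write_gfa(graph, outdir / name, include_seq=False)

    if hifi_only or not ul_reads:
        g = hifi_graph.build_string_graph(hifi_reads, overlaps, keep_contained=False)
        _dump(g, "reads_raw.gfa")
        hifi_graph.transitive_reduction(g, cfg.fuzz)
        _dump(g, "reads_reduced.gfa")
        hifi_graph.clean_graph(g, tip_len, cfg.min_edge_reads)
        _dump(g, "reads_cleaned.gfa")
        unitigs, ug = hifi_graph.make_unitigs(g)
        contigs = []
        critical: set = set()
        log.info("hifi_graph (accurate-only): %d unitigs", len(unitigs))
    else:
        g0 = hifi_graph.build_string_graph(hifi_reads, overlaps, keep_contained=True)
        hifi_graph.transitive_reduction(g0, cfg.fuzz)
        _u0, ug0 = hifi_graph.make_unitigs(g0)
        aligns0, _un0 = ul_align.align_ul(ul_reads, ug0, cfg.ul_align)
        covered, _rest = ul_align.rescue_contained(
            aligns0, ug0, contained, cfg.min_rescue)
        critical = ul_align.essential_contained(
            overlaps, covered, {r.id: len(r.seq) for r in hifi_reads}, contained)
        removable = contained - critical
        log.info("rescue: %d UL-covered candidates, %d critical / %d removable",
                 len(covered), len(critical), len(removable))
        g = hifi_graph.build_string_graph(hifi_reads, overlaps,
                                          keep_contained=True, drop=removable)
        _dump(g, "reads_raw.gfa")
        hifi_graph.transitive_reduction(g, cfg.fuzz)
        _dump(g, "reads_reduced.gfa")
        hifi_graph.clean_graph(g, tip_len, cfg.min_edge_reads)
        _dump(g, "reads_cleaned.gfa")
        unitigs, ug = hifi_graph.make_unitigs(g)
        log.info("hifi_graph: %d unitigs", len(unitigs))

        aligns, unaligned = ul_align.align_ul(ul_reads, ug, cfg.ul_align)
        iseqs = ul_align.encode_integer(aligns)
        ul_align.compute_edge_support(iseqs, ug)
        ul_align.weighted_clean(ug, cfg.min_support)
        write_paf(ul_align.chains_to_paf(aligns, ul_reads, ug), outdir / "ul_chains.paf")
        ul_align.write_integer_seqs(iseqs, outdir / "integer_seqs.tsv")
        log.info("ul_align: %d aligned, %d unaligned", len(aligns), len(unaligned))

        iovs = integer_graph.integer_overlaps(iseqs, cfg.min_iov)
        ig = integer_graph.build_integer_graph(iseqs, iovs)
        integer_graph.aggressive_clean(ig, cfg.tip_nodes)
        contigs = integer_graph.integer_contigs(ig)
        integer_graph.write_integer_contigs(contigs, outdir / "integer_contigs.tsv")
        _dump(ig, "integer_graph.gfa")
        log.info("integer_graph: %d overlaps, %d contigs", len(iovs), len(contigs))
        result["integer_graph"] = ig

    merged = merge_phase.incorporate(ug, contigs)
    write_gfa(ug, outdir / "unitigs.gfa")
    log.info("merge: %d nodes (%d contig-backed) in final graph",
             len(merged.nodes),
             sum(1 for n in merged.nodes.values() if n.origin == "contig"))

    sources = [genome.haplotypes[h] for h in range(genome.ploidy)]
    marker_sets = merge_phase.build_markers(sources, cfg.marker_k)
    counts = merge_phase.assign_markers(merged, marker_sets)
    with open(outdir / "marker_counts.tsv", "w") as fh:
        fh.write("node\torigin\t" + "\t".join(ms.label for ms in marker_sets) + "\n")
        for nid in sorted(counts, key=str):
            fh.write(f"{nid}\t{merged.nodes[nid].origin}\t"
                     + "\t".join(str(int(c)) for c in counts[nid]) + "\n")
    assemblies = {}
    metrics = []
    for h, ms in enumerate(marker_sets):
        asm = merge_phase.graph_binning(merged, counts, ms.label, marker_sets,
                                        cfg.min_markers, cfg.dom_ratio)
        assemblies[ms.label] = asm
        write_seqs(asm.contigs, outdir / f"{ms.label}.fasta")
        m = evaluate.truth_metrics(asm, genome.haplotypes[h],
                                   cfg.genome.telomere_motif,
                                   cfg.eval_min_len, cfg.eval_mode)
        metrics.append(m)
        log.info("binning %s: %d contigs, n50=%d, coverage=%.4f, switches=%d",
                 ms.label, m.n_contigs, m.n50, m.coverage, m.switch_errors)
    evaluate.write_metrics(metrics, outdir / "metrics.tsv")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump({m.label: m.as_dict() for m in metrics}, fh, indent=2,
                  sort_keys=True)
    write_gfa(merged, outdir / "final.gfa")

    result.update({
        "overlaps": overlaps, "contained": contained, "critical": critical,
        "unitigs": unitigs, "unitig_graph": ug, "contigs": contigs,
        "merged": merged, "assemblies": assemblies,
        "metrics": {m.label: m for m in metrics},
    })
    return result
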