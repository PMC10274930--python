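# dgasm — double-graph hybrid assembly of accurate and ultra-long reads

`dgasm` is a desk-scale, fully tested implementation of the double-graph
hybrid assembly strategy for haplotype-resolved genomes: accurate long reads
(HiFi-like) provide a base-accurate string-graph backbone, and ultra-long
noisy reads (ONT-UL-like, 5–10× longer) provide the long-range information
needed to walk through exact repeats and homozygous regions that the
accurate reads cannot span. It is aimed at people studying assembly-graph
algorithms — the contained-read problem, ultra-long-guided graph cleaning,
integer-space assembly, polyploid graph-binning — on simulated genomes where
every intermediate can be checked against ground truth.

## The algorithm

1. **Backbone string graph.** All-vs-all overlaps among accurate reads
   (minimizer seeding, banded verification); nodes are reads, edges are
   dovetail overlaps; Myers-style transitive reduction; conservative
   cleaning; unitigs = maximal non-branching paths.
2. **Contained-read rescue.** A read Y wholly covered by an overlap with a
   longer read X is *contained* and classically discarded — but if X carries
   another haplotype's alleles at its tips, dropping Y breaks Y's haplotype
   walk. `dgasm` keeps contained reads provisionally, aligns ultra-long
   reads to the graph, and retains exactly the contained reads that
   ultra-long alignment paths must traverse and whose removal would
   disconnect their neighbourhood.
3. **Edge weighting.** Each backbone edge is weighted by the number of
   distinct ultra-long reads whose alignment paths cross it; zero-support
   competitors of supported edges are cut instead of relying on
   longest-overlap heuristics alone.
4. **Integer graph.** Every ultra-long read is projected onto its alignment
   path — an ordered list of oriented unitig identifiers. A second string
   graph is built over these integer sequences with *exact* overlaps only
   (the graph alignment already removed the base errors), cleaned
   aggressively, and its non-branching paths become integer contigs: walks
   of the backbone far longer than any single read.
5. **Incorporation and binning.** Backbone unitigs that appear on integer
   contigs are replaced by the contigs; haplotype-specific k-mer markers
   (trio-style or per-haplotype sources) label the nodes, and each
   haplotype's assembly is emitted by discarding nodes dominated by other
   haplotypes' markers — the same rule for diploid and polyploid genomes.

A built-in simulator generates diploid/polyploid genomes with SNV
heterozygosity, exact interspersed repeats, homozygous segments, telomere
motifs, and both read types with truth provenance in the read names, so the
whole pipeline is testable without any external data.

## Worked example

A diploid 140 kb chromosome with two exact copies of an 18 kb repeat — far
longer than the 6 kb accurate reads, easily spanned by the 35 kb ultra-long
reads:

```yaml
# example.yaml
seed: 42
genome:
  ploidy: 2
  chrom_lengths: [140000]
  het_rate: 0.005
  repeats:
    - unit_len: 18000
      loci: [[0, 30000], [0, 85000]]
hifi: {mean_len: 6000, len_sd: 2000, min_len: 2000, coverage: 10.0}
ul: {mean_len: 35000, len_sd: 8000, min_len: 18000, coverage: 12.0}
overlap: {k: 21, min_ovlp: 1500, max_div: 0.0}
```

```text
$ dgasm -v run --config example.yaml --outdir out
INFO dgasm: simulate: ploidy=2 genome=140000bp hifi_reads=466
INFO dgasm: overlap: 6089 overlaps, 324 contained reads
INFO dgasm: rescue: 69 UL-covered candidates, 0 critical / 324 removable
INFO dgasm: hifi_graph: 7 unitigs
INFO dgasm: ul_align: 96 aligned, 0 unaligned
INFO dgasm: integer_graph: 1883 overlaps, 2 contigs
INFO dgasm: merge: 2 nodes (2 contig-backed) in final graph
hap1    n_contigs=1     n50=138094      coverage=0.9864 switches=0
hap2    n_contigs=1     n50=138705      coverage=0.9908 switches=0

$ dgasm run --config example.yaml --outdir out_hifi_only --hifi-only
hap1    n_contigs=4     n50=40586       coverage=0.9864 switches=0
hap2    n_contigs=4     n50=41729       coverage=0.9908 switches=0
```

The accurate reads alone collapse the two repeat copies into one 17 kb
unitig with four entries and four exits, so each haplotype fragments into
four contigs (N50 ≈ 41 kb). The ultra-long reads, encoded as integer
sequences over the 7 backbone unitigs, assemble into one integer contig per
haplotype that walks `arm → repeat → arm → repeat → arm`, and each haplotype
is emitted as a single contig covering ~99 % of its truth sequence with zero
switch errors. `out/` contains the per-haplotype FASTAs, the unitig and
final graphs as GFA 1.0 (ultra-long support in `ul:i:` tags), the ultra-long
chains as PAF, the integer sequences/contigs as TSV and a metrics table.

The library surface mirrors the pipeline: `simulate`, `overlap`,
`hifi_graph`, `ul_align`, `integer_graph`, `merge_phase`, `evaluate` can be
driven from Python for finer-grained experiments (see `dgasm.examples` for
two small worked fixtures, including the twelve-read contained-read example
with its seven ultra-long reads).

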