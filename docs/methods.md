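# Methods

## Model and assumptions

`dgasm` assembles a diploid or polyploid genome from two read classes: base-
accurate long reads (the backbone class) and much longer, originally noisy
ultra-long reads (the bridging class). The central objects are two string
graphs. The first is bidirected and built over accurate reads: each node is
a read, each edge a dovetail overlap, and the pair of arc statements
`(a,ao)→(b,bo)` / `(b,~bo)→(a,~ao)` is one edge. The second is a string
graph in *integer space*: its sequences are ordered lists of oriented unitig
identifiers obtained by aligning each ultra-long read to the backbone and
discarding all base-level detail. Because the backbone supplies the bases,
integer-space overlaps can be required to be exact, and integer contigs —
maximal non-branching paths — are walks of the backbone that can be spelled
back into base sequence with no consensus step.

The package assumes substitution-only errors. Accurate reads default to
error-free (base-level self-correction of real accurate reads is a separate,
upstream problem that this package does not model); ultra-long reads may
carry substitution errors, which the minimizer-anchor aligner absorbs. There
is no indel handling anywhere: overlap verification is banded exact
comparison on a fixed diagonal, which is the correct model for the simulator
and keeps every kernel checkable against brute force. `N` bases are treated
as mismatching everything, including another `N`.

## Stages and parameters

**Overlap detection** (`overlap`). Candidates come from shared minimizers
(window-start scheme: the argmin of every window of `w` consecutive k-mer
positions is selected, so any two occurrences of an identical substring of
at least `w+k-1` bases share a selected position — seeding provably loses
nothing on exact inputs). Each candidate `(pair, strand, diagonal)` is
verified over the full implied overlap region and kept only as a dovetail or
containment with `length ≥ min_ovlp` and divergence `≤ max_div`. One overlap
per unordered pair is reported: longest, then smaller `a_start`, then same
strand first. Defaults `k=21, min_ovlp=250, max_div=0.02`; the minimizer
window is derived as `(min_ovlp−k)//2` so the guarantee above holds at the
configured threshold. Pipeline configurations for 6–15 kb error-free reads
use `min_ovlp` of 1500–2000 and `max_div=0`: with per-base heterozygosity
around 0.005, a 2 kb exact match between haplotypes has probability
`exp(−0.005·2·2000) ≈ 10⁻⁹`, so cross-haplotype edges are confined to
genuinely homozygous sequence — the property the whole phasing strategy
rests on. At `max_div > 0` and low heterozygosity those guarantees weaken;
see Limitations.

**Backbone graph** (`hifi_graph`). Transitive reduction is Myers-style with
`fuzz = 10` bp (error-free simulation makes extensions near-exact); the
minimal-extension arc out of every node end is irreducible, so removed edges
remain realised by surviving walks. Cleaning is deliberately conservative:
dangling chains shorter than `tip_len` (default 3× the accurate mean read
length) are removed, and a parallel branch is popped only when it carries
fewer than `min_edge_reads = 2` reads while its partner carries at least
that many — heterozygous bubbles are phasing substrate and are never popped.
Branch resolution beyond that is deferred to ultra-long evidence.

**Contained reads.** Contained reads are kept as flagged nodes, wired by
their own genuine dovetail overlaps (with exact reads the reduction threads
them into chains, so ultra-long alignment paths can traverse them). Rescue
is two-staged. First the specified coverage rule: a contained read is a
candidate if at least `min_rescue = 2` distinct ultra-long chains traverse a
node interval containing its placement (±50 bp anchor slack). Second,
junction essentiality: candidates are visited shortest-first and dropped
whenever their overlap partners remain mutually connected without them. The
refinement exists because the coverage rule alone keeps every contained read
that the reduction threaded into a chain (a third of all reads at ordinary
coverage), which re-fragments the rebuilt graph at every container; what
survives the essentiality pass is exactly the minimal bridge set — contained
reads whose container carries another haplotype's alleles at its tips and
which therefore patch a haplotype breakpoint. After rescue the backbone is
rebuilt from scratch from the retained read set (deleting a mid-chain node
from a reduced graph would orphan its neighbours, because their direct
overlap was itself reduced away).

**Ultra-long alignment** (`ul_align`). Minimizer anchors (`k=17, w=11`, all
node k-mer positions indexed, query minimizers sampled) are clustered per
oriented node on their diagonal (band 500 bp) into segments of at least
`min_anchors = 3`; segments are chained by dynamic programming where a
transition must be a graph edge and must be gap-consistent within
`max_gap = 2000` bp; the score is 100× newly-covered anchors minus the gap
inconsistency in bp. Ties prefer fewer nodes, then larger total node length,
then the lexicographically smallest path — a chain that skips a redundant
contained node therefore wins at equal coverage. Finally, terminal chain
segments whose anchors are matched to within `ambiguity_ratio = 0.98` by a
competing extension at the same junction are trimmed: where both branches at
a junction begin with the same sequence (repeat overhangs absorbed into
flanking unitigs), a read ending inside that shared stretch cannot resolve
the branch, and committing to either arm would fabricate a walk. The 0.98
threshold separates "identical sequence" (anchor counts equal) from "the
homologous haplotype arm" (≈10 % of 17-mers broken by SNVs at het 0.005).

**Edge support and weighted cleaning.** `ul_support(e)` counts distinct
ultra-long reads whose integer sequence contains `e` in either direction. At
any node side with several edges, if at least one edge reaches
`min_support = 1`, all zero-support competitors are cut; if none does, the
longest-overlap edge is kept (the classical heuristic, used only where
ultra-long evidence is silent). Competing supported edges are all kept —
that ambiguity belongs to the integer graph. The re-collapse after cleaning
is deferred: cut edges always have zero support, so integer sequences remain
valid walks over the same unitig alphabet, and the final collapse happens at
merged-graph emission with an identical result.

**Integer graph** (`integer_graph`). Overlaps are exact suffix–prefix
matches of at least `min_iov = 1` oriented element (unitigs are long, so one
shared element is already highly specific); containment of an integer
sequence shadows its dovetails and contained sequences are dropped
unconditionally — an ultra-long read is unlikely to be a critical contained
read. Transitive reduction uses fuzz 0 (exactness is the invariant).
Aggressive cleaning keeps, on every crowded node side, only the best edge
(longest overlap, ties to the longer neighbour, then the smaller id),
removes integer tips of at most `tip_nodes = 2` nodes, drops nodes orphaned
by the cuts, and iterates to a fixed point. Contigs are emitted in canonical
orientation (the lexicographically smaller of a path and its reverse).

**Incorporation and binning** (`merge_phase`). Unitigs appearing on any
integer contig leave the residual set; contig nodes are spelled by walking
the backbone (first node's oriented sequence, then each successor beyond the
edge overlap); boundary edges are reconstructed from backbone edges at
contig path ends, both contig–residual and contig–contig, and a unitig
shared by several contigs legitimately backs several nodes. Markers are
canonical 31-mers unique to one haplotype source (sources are the truth
haplotypes in simulation mode — trio binning with perfect parents; the sets
are pairwise disjoint by construction). A node is assigned to a haplotype
when its top marker count is at least `min_markers = 2` and at least
`dom_ratio = 2` times the runner-up; unassigned nodes are emitted in every
haplotype (homozygous sequence belongs to all of them). Emission deletes
every node dominated by another haplotype and spells the surviving maximal
non-branching paths; ploidy 2 and higher use the same rule.

**Evaluation** (`evaluate`). N50; contig counts with a configurable length
filter (default 5 kb — the genome-scale convention of filtering small
contigs, scaled to simulation size); truth coverage by exact tiling of
contigs onto their haplotype (error-free mode) or canonical k-mer
containment; switch errors as adjacent marker-label flips along each
contig's node path; telomere-to-telomere counting by motif presence within
200 bp of both contig ends.

## The simulator, and what the tests do and do not show

`simulate` draws i.i.d. uniform base sequence, plants exact repeat units at
given loci (a single-locus "repeat" doubles as an exact homozygous segment),
stamps telomere motifs on chromosome ends, and derives each further
haplotype by substituting SNVs at `het_rate` per base outside repeat and
telomere intervals. Reads have truncated-normal lengths, uniform starts and
strands, and optional substitution errors; provenance travels in the read
name. Read counts are `coverage × length / mean_len`, so total bases track
coverage within sampling noise.

This emulates the *structural* challenges of hybrid assembly — repeats
longer than accurate reads, homozygous corridors, haplotype mosaics,
contained-read criticality — but not sequencing reality: no indels, no
homopolymer artifacts, no coverage or strand bias, no chimeras, no
structural variation between haplotypes, and uniform rather than
length-biased sampling. Passing tests therefore demonstrate the graph
algorithms and their interplay, not robustness to real instrument noise.

Two deterministic fixtures reproduce the contained-read mechanism exactly.
The twelve-read example (`examples.contained_read_example`) lays out two
haplotypes around an exact homozygous middle; the long read h3 spans that
middle but carries haplotype-1 flanking sequence at both tips, so haplotype
2 can cross only through the contained read h12 (covered by ultra-long reads
u6 and u7, hence rescued), while the contained h11 is skippable and removed;
the (h5,h8) junction is crossed by u4 and u5, giving that edge weight 2. The
tiled fixture (`examples.contained_rescue_fixture`) scales the same geometry
to a 150 kb simulated diploid: accurate reads are tiled deterministically
(6 kb reads, 2 kb stride) with a 12 kb homozygous corridor left uncovered
except for a haplotype-1 spanner and a purely homozygous contained bridge.
The tiling is deliberate: under uniform sampling, a component severance that
contained-read rescue can heal is a coin-flip event (a container always
bridges its own haplotype, and pooled homozygous interiors bridge the rest),
so the fixture constructs the phenomenon it exists to test instead of
waiting for it.

## Problem sizes

The test and acceptance workloads use diploid genomes of 40–500 kb (and a
4×100 kb tetraploid), accurate reads of 6–15 kb at 10× per haplotype, and
ultra-long reads of 25–80 kb at 10–12× per haplotype; oracle-equivalence
checks run on 100 random instances per kernel at up to 40 reads / 50 integer
sequences. These sizes keep every brute-force oracle exact and the whole
suite in a few minutes on one core while preserving the length hierarchy
(repeat unit ≫ accurate read, ultra-long read ≫ repeat unit) that the
method is about.

## Numerical and degenerate-input choices

Equal-length mutually-contained reads: the later read in input order is the
contained one. Containment shadows dovetails for a pair; per pair exactly
one overlap is kept. Minimizer selection hashes canonical k-mers with a
splitmix64 finaliser truncated to 31 bits (scipy's filters traverse float64;
31-bit keys are exact there, and the rare tie only broadens selection
symmetrically on both copies of a substring). Empty inputs: no reads → no
overlaps; no ultra-long data → every contained read removable and the
pipeline degenerates to the classical accurate-only string graph; an empty
contig set makes the merged graph isomorphic to the backbone. N50 of an
empty assembly is reported as 0 by the metrics record, while `n50()` itself
rejects empty input. All randomness flows from explicit integer seeds;
output files iterate sorted collections, so identical configurations yield
byte-identical artifacts.

## Known limitations

- Substitution-only throughout; no indel-tolerant alignment.
- No base-level error correction of accurate reads; `max_div` absorbs
  residual error, which at low heterozygosity can admit cross-haplotype
  overlaps — the error-free configurations avoid this by `max_div=0`.
- Hi-C phasing is out of scope; binning requires per-haplotype or parental
  marker sources.
- Circular chromosomes are collapsed with an arbitrary (deterministic) break
  point and no explicit circularity flag.
- The ultra-long aligner returns one best chain per read; reads whose best
  and second-best routes tie beyond the ambiguity trim (e.g. a read entirely
  inside a repeat) contribute a shortened or empty integer sequence rather
  than a multi-placement.
- Contained-read rescue tests undirected neighbourhood connectivity, a
  slight relaxation of bidirected walk-consistency; on the fixtures and
  simulations exercised here the two coincide.
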