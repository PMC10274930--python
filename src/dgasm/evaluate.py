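"""Assembly metrics against simulator truth.

Contiguity (N50, contig counts with a scaled length filter), per-haplotype
truth coverage by exact tiling (error-free mode) or k-mer containment,
switch errors as marker-label flips along each contig's node path, and
telomere-to-telomere contig counting by terminal motif presence.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import numpy as np

from ._kmer import canonical_kmer_set, revcomp
from .errors import ValidationError
from .merge_phase import HaplotypeAssembly


@dataclass
class AssemblyMetrics:
    label: str
    n_contigs: int
    n_contigs_ge_min: int
    total_len: int
    n50: int
    coverage: float
    switch_errors: int
    t2t_count: int

    def as_dict(self) -> dict:
        return asdict(self)


def n50(lengths: Iterable[int]) -> int:
    """Largest L such that contigs of length >= L hold half the total bases."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValidationError("n50 of an empty length list")
    if min(lengths) <= 0:
        raise ValidationError("n50 requires positive lengths")
    half = sum(lengths) / 2
    acc = 0
    for L in lengths:
        acc += L
        if acc >= half:
            return L
    return lengths[-1]


def _covered_fraction_exact(contigs, truth_chroms) -> float:
    total = sum(len(c) for c in truth_chroms)
    masks = [np.zeros(len(c), bool) for c in truth_chroms]
    for rec in contigs:
        for seq in (rec.seq, revcomp(rec.seq)):
            for ci, chrom in enumerate(truth_chroms):
                start = chrom.find(seq)
                while start != -1:
                    masks[ci][start : start + len(seq)] = True
                    start = chrom.find(seq, start + 1)
    return sum(int(m.sum()) for m in masks) / total


def _covered_fraction_kmer(contigs, truth_chroms, k: int = 31) -> float:
    truth = canonical_kmer_set(truth_chroms, k)
    if truth.size == 0:
        return 0.0
    asm = canonical_kmer_set([c.seq for c in contigs], k) if contigs else None
    if asm is None or asm.size == 0:
        return 0.0
    idx = np.searchsorted(asm, truth)
    idx[idx == asm.size] = asm.size - 1
    return float(np.count_nonzero(asm[idx] == truth)) / truth.size


def _has_telomere(seq: str, motif: str, window: int = 200) -> bool:
    rc = revcomp(motif)
    head, tail = seq[:window], seq[-window:]
    return ((motif in head or rc in head) and (motif in tail or rc in tail))


def switch_errors(provenance) -> int:
    """Adjacent marker-label flips along each contig's node path."""
    flips = 0
    for path in provenance:
        labels = [lab for _n, _o, lab in path if lab is not None]
        flips += sum(1 for a, b in zip(labels, labels[1:]) if a != b)
    return flips


def truth_metrics(assembly: HaplotypeAssembly, truth_chroms: list[str],
                  telomere_motif: Optional[str] = None, min_len: int = 5000,
                  mode: str = "exact") -> AssemblyMetrics:
    """Score one haplotype's emission against its truth haplotype."""
    if not truth_chroms:
        raise ValidationError("truth_metrics requires the truth haplotype")
    contigs = assembly.contigs
    lengths = [len(c) for c in contigs]
    if mode == "exact":
        cov = _covered_fraction_exact(contigs, truth_chroms) if contigs else 0.0
    else:
        cov = _covered_fraction_kmer(contigs, truth_chroms)
    t2t = 0
    if telomere_motif:
        t2t = sum(1 for c in contigs if _has_telomere(c.seq, telomere_motif))
    return AssemblyMetrics(
        label=assembly.label,
        n_contigs=len(contigs),
        n_contigs_ge_min=sum(1 for L in lengths if L >= min_len),
        total_len=sum(lengths),
        n50=n50(lengths) if lengths else 0,
        coverage=cov,
        switch_errors=switch_errors(assembly.provenance),
        t2t_count=t2t,
    )


def write_metrics(metrics: list[AssemblyMetrics], path) -> None:
    cols = ["label", "n_contigs", "n_contigs_ge_min", "total_len", "n50",
            "coverage", "switch_errors", "t2t_count"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for m in metrics:
            d = m.as_dict()
            fh.write("\t".join(str(d[c]) for c in cols) + "\n")
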