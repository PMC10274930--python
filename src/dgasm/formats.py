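"""Readers and writers for FASTA, FASTQ, GFA 1.0 and PAF.

All coordinates are 0-based half-open internally; PAF and GFA conventions are
honoured at the file boundary. GFA links are emitted once per bidirected edge
in canonical orientation, with the overlap as an ``<int>M`` CIGAR and the
ultra-long support count in a ``ul:i:`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ConsistencyError, ParseError, ValidationError
from .graph import StringGraph


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with FASTQ qualities."""

    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.seq:
            raise ValidationError(f"record {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValidationError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)


def read_seqs(path, format: Optional[str] = None) -> list[SeqRecord]:
    """Read FASTA/FASTQ records in file order, uppercased and id-checked."""
    path = Path(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    if format not in {"fasta", "fastq"}:
        raise ValidationError(f"unsupported format {format!r}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    try:
        with open(path) as fh:
            if format == "fasta":
                for title, seq in SimpleFastaParser(fh):
                    records.append(SeqRecord(title.split()[0], seq.upper()))
            else:
                for title, seq, qual in FastqGeneralIterator(fh):
                    records.append(SeqRecord(title.split()[0], seq.upper(), qual))
    except ValueError as exc:  # Biopython's structural errors
        raise ParseError(
            f"{path}: malformed {format} near record {len(records) + 1} "
            f"(~line {_approx_line(format, len(records))}): {exc}") from exc
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def _approx_line(format: str, n_parsed: int) -> int:
    return n_parsed * (4 if format == "fastq" else 2) + 1


def write_seqs(records: Iterable[SeqRecord], path, format: Optional[str] = None,
               width: int = 80) -> None:
    path = Path(path)
    if format is None:
        format = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    with open(path, "w") as fh:
        for rec in records:
            if format == "fasta":
                fh.write(f">{rec.id}\n")
                for i in range(0, len(rec.seq), width):
                    fh.write(rec.seq[i : i + width] + "\n")
            else:
                qual = rec.qual if rec.qual is not None else "I" * len(rec.seq)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def write_gfa(graph: StringGraph, path, include_seq: bool = True) -> None:
    """Serialise a string graph as GFA 1.0.

    One S line per node (``ct:i:1`` marks contained nodes, ``or:Z:`` the
    merged-graph origin, ``el:Z:`` integer-space element lists), one L line
    per bidirected edge in canonical orientation with a ``ul:i:`` support tag.
    """
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for nid in sorted(graph.nodes, key=str):
            n = graph.nodes[nid]
            seq = n.seq if (include_seq and n.seq) else "*"
            tags = [f"LN:i:{n.length}"]
            if n.contained:
                tags.append("ct:i:1")
            if n.origin:
                tags.append(f"or:Z:{n.origin}")
            if n.payload:
                tags.append("el:Z:" + ",".join(f"{e}{o}" for e, o in n.payload))
            fh.write(f"S\t{nid}\t{seq}\t" + "\t".join(tags) + "\n")
        lines = []
        for a, ao, b, bo, ov in graph.edges():
            sup = graph.get_support(a, ao, b, bo)
            lines.append((str(a), ao, str(b), bo, ov, sup))
        for a, ao, b, bo, ov, sup in sorted(lines):
            fh.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{ov}M\tul:i:{sup}\n")


def read_gfa(path) -> StringGraph:
    """Parse GFA 1.0 written by :func:`write_gfa` (node ids become strings)."""
    g = StringGraph()
    links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "H#":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: truncated S line")
                name, seq = fields[1], fields[2]
                length = None if seq != "*" else 0
                contained = False
                payload = None
                origin = None
                for tag in fields[3:]:
                    if tag.startswith("LN:i:"):
                        length = int(tag[5:])
                    elif tag == "ct:i:1":
                        contained = True
                    elif tag.startswith("or:Z:"):
                        origin = tag[5:]
                    elif tag.startswith("el:Z:"):
                        payload = tuple(
                            (p[:-1], p[-1]) for p in tag[5:].split(","))
                g.add_node(name, length=length if seq == "*" else len(seq),
                           seq=None if seq == "*" else seq,
                           contained=contained, payload=payload, origin=origin)
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise ParseError(f"{path}:{lineno}: truncated L line")
                a, ao, b, bo, cig = fields[1:6]
                if ao not in "+-" or bo not in "+-":
                    raise ParseError(f"{path}:{lineno}: bad orientation")
                if not cig.endswith("M"):
                    raise ParseError(f"{path}:{lineno}: unsupported CIGAR {cig!r}")
                sup = 0
                for tag in fields[6:]:
                    if tag.startswith("ul:i:"):
                        sup = int(tag[5:])
                links.append((a, ao, b, bo, int(cig[:-1]), sup, lineno))
    for a, ao, b, bo, ov, sup, lineno in links:
        if a not in g.nodes or b not in g.nodes:
            raise ConsistencyError(f"{path}:{lineno}: link references unknown segment")
        g.add_edge(a, ao, b, bo, ov)
        g.set_support(a, ao, b, bo, sup)
    return g


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

@dataclass
class PafRecord:
    """One PAF line (coordinates 0-based half-open, strand '+'/'-')."""

    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    alnlen: int
    mapq: int = 255
    tags: dict = field(default_factory=dict)


def write_paf(records: Iterable[PafRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [r.qname, r.qlen, r.qstart, r.qend, r.strand,
                    r.tname, r.tlen, r.tstart, r.tend, r.nmatch, r.alnlen, r.mapq]
            for key, val in sorted(r.tags.items()):
                typ = "i" if isinstance(val, int) else "Z"
                cols.append(f"{key}:{typ}:{val}")
            fh.write("\t".join(str(c) for c in cols) + "\n")


def read_paf(path) -> list[PafRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: PAF line has {len(f)} columns")
            tags = {}
            for tag in f[12:]:
                key, typ, val = tag.split(":", 2)
                tags[key] = int(val) if typ == "i" else val
            out.append(PafRecord(f[0], int(f[1]), int(f[2]), int(f[3]), f[4],
                                 f[5], int(f[6]), int(f[7]), int(f[8]),
                                 int(f[9]), int(f[10]), int(f[11]), tags))
    return out
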