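"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: usage problems exit 2 (click's default),
data/consistency problems exit 3.
"""


class DgasmError(Exception):
    """Base class for all package errors."""


class ParseError(DgasmError):
    """A file could not be parsed (malformed FASTA/FASTQ/GFA/PAF)."""


class ValidationError(DgasmError):
    """An input object violates its documented invariants."""


class ConsistencyError(DgasmError):
    """Internal cross-references disagree (edge to unknown node, etc.)."""
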