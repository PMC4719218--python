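"""Reference genome container and variant-token helpers.

Coordinates are 1-based and inclusive throughout the package, matching
pileup files and the rCRS numbering convention used for human mtDNA.
The genome is circular biologically, but because the entry point of the
pipeline is per-position pileup data, positions are plain ``1..L``
integers and no wraparound arithmetic is ever needed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputContractError, InvalidParameterError

#: Canonical base ordering used for every count matrix in the package.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_TOKEN_RE = re.compile(r"^(\d+)([ACGT])$")


@dataclass(frozen=True)
class ReferenceGenome:
    """A single circular reference sequence over the {A,C,G,T} alphabet."""

    name: str
    sequence: str
    circular: bool = True
    length: int = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if set(seq) - set(BASES):
            bad = sorted(set(seq) - set(BASES))
            raise InvalidParameterError(
                f"reference sequence contains non-ACGT symbols: {bad}"
            )
        object.__setattr__(self, "length", len(seq))

    def base(self, position: int) -> str:
        """Reference base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise InputContractError(
                f"position {position} outside reference [1, {self.length}]"
            )
        return self.sequence[position - 1]


def parse_variant_token(token: str) -> tuple[int, str]:
    """Parse a ``<position><base>`` token such as ``'73G'`` into ``(73, 'G')``."""
    m = _TOKEN_RE.match(token.strip().upper())
    if m is None:
        raise InputContractError(f"malformed variant token {token!r}")
    return int(m.group(1)), m.group(2)


def format_variant_token(position: int, allele: str) -> str:
    return f"{position}{allele}"


def read_reference_fasta(path) -> ReferenceGenome:
    """Load the first (and only expected) record of a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise InputContractError(
            f"expected exactly one reference record in {path}, found {len(records)}"
        )
    rec = records[0]
    return ReferenceGenome(name=rec.id, sequence=str(rec.seq))


def write_reference_fasta(reference: ReferenceGenome, path) -> None:
    rec = SeqRecord(Seq(reference.sequence), id=reference.name, description="")
    SeqIO.write([rec], str(path), "fasta")
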