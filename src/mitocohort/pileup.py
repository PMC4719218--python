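"""Strand-specific pileup parsing and sequence-format writers.

The pipeline's sequence-level input is a pair of SAMtools-mpileup text
files per individual: one generated from forward-strand reads and one
from reverse-strand reads. Only a restricted dialect of the read-bases
column is supported — match symbols (``.``/``,``) and substitution
symbols (``ACGTacgt``). Indel tokens, read start/end markers and
deletion placeholders are rejected loudly: the pipeline analyses
substitutions only and expects upstream QC to have removed everything
else.

Positions absent from a pileup file have zero counts on that strand;
this is the package's convention for zero-coverage sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputContractError, PileupParseError
from .genome import BASES, BASE_INDEX, ReferenceGenome, format_variant_token

logger = logging.getLogger(__name__)

_ALLOWED = set(".,ACGTacgt")
_REJECTED_HINTS = set("+-^$*<>Nn")


@dataclass
class StrandPileup:
    """Per-position, per-strand base counts for one individual.

    ``fwd`` and ``rev`` are ``(L, 4)`` integer matrices in A,C,G,T
    column order; row ``i`` is 1-based position ``i + 1``.
    """

    individual_id: str
    reference_name: str
    fwd: np.ndarray
    rev: np.ndarray

    def __post_init__(self) -> None:
        self.fwd = np.asarray(self.fwd, dtype=np.int64)
        self.rev = np.asarray(self.rev, dtype=np.int64)
        if self.fwd.shape != self.rev.shape or self.fwd.ndim != 2 or self.fwd.shape[1] != 4:
            raise InputContractError(
                f"strand count matrices must share an (L, 4) shape, got "
                f"{self.fwd.shape} and {self.rev.shape}"
            )
        if (self.fwd < 0).any() or (self.rev < 0).any():
            raise InputContractError("negative base counts")

    @property
    def length(self) -> int:
        return self.fwd.shape[0]

    def forward_depth(self) -> np.ndarray:
        return self.fwd.sum(axis=1)

    def reverse_depth(self) -> np.ndarray:
        return self.rev.sum(axis=1)


def _parse_one_file(path, reference: ReferenceGenome) -> tuple[str | None, np.ndarray]:
    counts = np.zeros((reference.length, 4), dtype=np.int64)
    chrom_seen: str | None = None
    seen_positions: set[int] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PileupParseError(
                    f"{path}:{lineno}: expected 6 pileup columns, got {len(fields)}"
                )
            chrom, pos_s, refbase, depth_s, bases = fields[0], fields[1], fields[2], fields[3], fields[4]
            if chrom_seen is None:
                chrom_seen = chrom
            elif chrom != chrom_seen:
                raise PileupParseError(
                    f"{path}:{lineno}: multiple reference names in one file "
                    f"({chrom_seen!r} then {chrom!r})"
                )
            try:
                pos = int(pos_s)
                depth = int(depth_s)
            except ValueError as exc:
                raise PileupParseError(f"{path}:{lineno}: non-integer field") from exc
            if not 1 <= pos <= reference.length:
                raise PileupParseError(
                    f"{path}:{lineno}: position {pos} outside reference "
                    f"[1, {reference.length}]"
                )
            if pos in seen_positions:
                raise PileupParseError(f"{path}:{lineno}: duplicate position {pos}")
            seen_positions.add(pos)
            refbase = refbase.upper()
            if refbase != reference.base(pos):
                raise PileupParseError(
                    f"{path}:{lineno}: reference base {refbase!r} at position {pos} "
                    f"disagrees with the reference sequence ({reference.base(pos)!r})"
                )
            bad = set(bases) - _ALLOWED
            if bad:
                detail = "indel/read-boundary tokens" if bad & _REJECTED_HINTS else "symbols"
                raise PileupParseError(
                    f"{path}:{lineno}: unsupported {detail} in read-bases column: "
                    f"{sorted(bad)}"
                )
            row = counts[pos - 1]
            row[BASE_INDEX[refbase]] += bases.count(".") + bases.count(",")
            for b in BASES:
                row[BASE_INDEX[b]] += bases.count(b) + bases.count(b.lower())
            counted = int(row.sum())
            if counted != depth:
                logger.warning(
                    "%s:%d: depth column %d disagrees with counted bases %d at position %d",
                    path, lineno, depth, counted, pos,
                )
    return chrom_seen, counts


def read_strand_pileups(
    forward_path,
    reverse_path,
    reference: ReferenceGenome,
    individual_id: str | None = None,
) -> StrandPileup:
    """Parse a forward/reverse pileup file pair into one count table.

    The two files must name the same reference sequence. ``.``/``,``
    symbols are resolved to the reference base at that position; base
    letters are counted case-insensitively.
    """
    fwd_chrom, fwd = _parse_one_file(forward_path, reference)
    rev_chrom, rev = _parse_one_file(reverse_path, reference)
    if fwd_chrom is not None and rev_chrom is not None and fwd_chrom != rev_chrom:
        raise InputContractError(
            f"forward file names reference {fwd_chrom!r} but reverse file names "
            f"{rev_chrom!r}"
        )
    name = fwd_chrom or rev_chrom or reference.name
    if individual_id is None:
        individual_id = str(forward_path)
    return StrandPileup(individual_id=individual_id, reference_name=name, fwd=fwd, rev=rev)


def write_consensus_fasta(profiles, path) -> None:
    """Write one FASTA record per consensus profile; missing sites become ``N``."""
    lengths = {len(p.alleles) for p in profiles}
    if len(lengths) > 1:
        raise InputContractError(f"profiles have differing lengths: {sorted(lengths)}")
    records = []
    for p in profiles:
        chars = np.array(list("N" + BASES))[p.alleles + 1]  # -1 -> 'N'
        records.append(
            SeqRecord(Seq("".join(chars)), id=p.individual_id, description="")
        )
    SeqIO.write(records, str(path), "fasta")


def write_hsd(variant_sets, range_string: str, path) -> None:
    """Write variant sets in the HSD haplogroup-classifier input format.

    One tab-separated row per individual: identifier, queried range, a
    ``?`` placeholder for the (unknown) haplogroup column, then variant
    tokens like ``73G`` in ascending position order.
    """
    with open(path, "w") as fh:
        for vs in variant_sets:
            tokens = [
                format_variant_token(pos, allele)
                for pos, allele in sorted(vs.variants)
            ]
            fh.write("\t".join([vs.individual_id, range_string, "?", *tokens]) + "\n")
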