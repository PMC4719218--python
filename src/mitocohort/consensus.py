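"""Consensus calling, variant extraction and pathogenicity screening.

The consensus allele at a position is the major allele by combined
forward + reverse count, subject to a per-strand coverage gate: a
position is called only when each strand individually reaches
``min_strand_depth`` (default 10×). Ties at the combined-count argmax
are left uncalled — a tie at consensus scale indicates an unresolved
site, which the heteroplasmy caller is the right tool for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InputContractError
from .genome import BASES, ReferenceGenome
from .pileup import StrandPileup

#: sentinel allele code for positions failing the coverage gate (or ties)
MISSING = -1


@dataclass
class ConsensusProfile:
    """Per-individual called alleles; code ``-1`` marks missing positions."""

    individual_id: str
    alleles: np.ndarray  # int8 codes into BASES, -1 = missing
    reference_name: str = ""

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)

    @property
    def missing_count(self) -> int:
        return int((self.alleles == MISSING).sum())

    def allele_at(self, position: int) -> str | None:
        code = self.alleles[position - 1]
        return None if code == MISSING else BASES[code]


@dataclass(frozen=True)
class VariantSet:
    """An individual's substitutions relative to the reference."""

    individual_id: str
    variants: frozenset[tuple[int, str]]

    @property
    def count(self) -> int:
        return len(self.variants)


def call_consensus(pileup: StrandPileup, min_strand_depth: int = 10) -> ConsensusProfile:
    """Call the major allele per position under the per-strand depth gate."""
    combined = pileup.fwd + pileup.rev
    called = combined.argmax(axis=1).astype(np.int8)
    top = combined.max(axis=1)
    tied = (combined == top[:, None]).sum(axis=1) > 1
    gate = (
        (pileup.forward_depth() >= min_strand_depth)
        & (pileup.reverse_depth() >= min_strand_depth)
        & ~tied
    )
    called[~gate] = MISSING
    return ConsensusProfile(
        individual_id=pileup.individual_id,
        alleles=called,
        reference_name=pileup.reference_name,
    )


def profile_from_sequence(individual_id: str, sequence: str,
                          reference_name: str = "") -> ConsensusProfile:
    """Rebuild a profile from an exported consensus sequence (``N`` = missing)."""
    lut = np.full(256, MISSING, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    codes = lut[np.frombuffer(sequence.upper().encode(), dtype=np.uint8)]
    return ConsensusProfile(
        individual_id=individual_id, alleles=codes, reference_name=reference_name
    )


def extract_variants(profile: ConsensusProfile, reference: ReferenceGenome) -> VariantSet:
    """Called positions whose allele differs from the reference base."""
    if len(profile.alleles) != reference.length:
        raise InputContractError(
            f"profile length {len(profile.alleles)} != reference length "
            f"{reference.length}"
        )
    ref_codes = np.frombuffer(reference.sequence.encode(), dtype=np.uint8)
    lut = np.full(256, MISSING, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    ref_codes = lut[ref_codes]
    diff = (profile.alleles != MISSING) & (profile.alleles != ref_codes)
    positions = np.flatnonzero(diff)
    variants = frozenset(
        (int(p) + 1, BASES[profile.alleles[p]]) for p in positions
    )
    return VariantSet(individual_id=profile.individual_id, variants=variants)


def read_pathogenic_table(path) -> pd.DataFrame:
    """Load a TSV of known pathogenic substitutions (position, allele, disease)."""
    table = pd.read_csv(path, sep="\t", dtype={"position": int, "allele": str})
    missing = {"position", "allele", "disease"} - set(table.columns)
    if missing:
        raise DataError(f"pathogenic table {path} missing columns {sorted(missing)}")
    if table.duplicated(["position", "allele"]).any():
        raise DataError(f"pathogenic table {path} has duplicate (position, allele) rows")
    return table


def screen_pathogenic(variants: VariantSet, table: pd.DataFrame) -> pd.DataFrame:
    """Exact (position, allele) intersection of a variant set with a lookup table."""
    if table.empty:
        return table.copy()
    keys = set(variants.variants)
    hit = [
        (int(row.position), str(row.allele)) in keys for row in table.itertuples()
    ]
    return table.loc[hit].reset_index(drop=True)


def average_pathogenicity(variants: VariantSet, scores: pd.DataFrame) -> float | None:
    """Mean per-variant pathogenicity score for one individual.

    ``scores`` maps (position, allele) to a raw score (TSV columns
    ``position``, ``allele``, ``score``). Returns ``None`` — not 0 — for
    an individual with no variants; raises if any variant lacks a score
    row.
    """
    if variants.count == 0:
        return None
    lookup = {
        (int(r.position), str(r.allele)): float(r.score) for r in scores.itertuples()
    }
    total = 0.0
    for pos, allele in variants.variants:
        try:
            total += lookup[(pos, allele)]
        except KeyError:
            raise DataError(
                f"no pathogenicity score for variant {pos}{allele} of "
                f"{variants.individual_id}"
            ) from None
    return total / variants.count
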