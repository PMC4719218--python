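"""Double-strand-validated heteroplasmy detection and burden statistics.

A heteroplasmy is a site where an individual carries a mixture of
mitochondrial genomes. Low-frequency minor alleles are hard to separate
from sequencing error, so calling is deliberately conservative:

* only positions with at least ``min_strand_depth`` (default 500×)
  coverage on *each* strand are usable;
* the minor allele (second-most-frequent by combined count) must reach
  ``min_minor_freq`` (default 1%, inclusive) on *each* strand
  independently — double-strand validation; a signal present on one
  strand only is discarded as an artifact;
* at most one call per position: only the largest minor allele is
  evaluated.

Because usable-site counts differ between individuals, per-individual
burden is expressed as heteroplasmies per usable site (HPUI), and group
comparisons use the rank-based Wilcoxon test on HPUI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, InputContractError
from .genome import BASES
from .pileup import StrandPileup


@dataclass(frozen=True)
class HeteroplasmyCall:
    individual_id: str
    position: int
    major: str
    minor: str
    fwd_freq: float
    rev_freq: float
    combined_freq: float


@dataclass(frozen=True)
class BurdenRecord:
    """Heteroplasmy burden of one individual; ``hpui`` is None when no site is usable."""

    individual_id: str
    count: int
    usable_sites: int
    hpui: float | None


@dataclass(frozen=True)
class SharingSpectrum:
    """Cohort-level sharing: carriers per heteroplasmic allele and per-individual counts."""

    carriers: pd.Series       # (position, minor) -> number of carriers
    per_individual: pd.Series  # individual_id -> number of calls


def usable_sites(pileup: StrandPileup, min_strand_depth: int = 500) -> set[int]:
    """1-based positions with at least the depth floor on both strands."""
    ok = (pileup.forward_depth() >= min_strand_depth) & (
        pileup.reverse_depth() >= min_strand_depth
    )
    return set((np.flatnonzero(ok) + 1).tolist())


def call_heteroplasmies(
    pileup: StrandPileup,
    min_minor_freq: float = 0.01,
    min_strand_depth: int = 500,
) -> list[HeteroplasmyCall]:
    """Detect double-strand-validated heteroplasmies in one individual."""
    if not 0 < min_minor_freq <= 0.5:
        raise InputContractError("min_minor_freq must be in (0, 0.5]")
    fwd_d = pileup.forward_depth()
    rev_d = pileup.reverse_depth()
    usable = (fwd_d >= min_strand_depth) & (rev_d >= min_strand_depth)
    combined = pileup.fwd + pileup.rev
    # rank alleles by combined count; argsort is stable so ties resolve
    # to the lower base index deterministically
    order = np.argsort(-combined, axis=1, kind="stable")
    major_idx = order[:, 0]
    minor_idx = order[:, 1]
    rows = np.arange(pileup.length)
    minor_comb = combined[rows, minor_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        f_freq = pileup.fwd[rows, minor_idx] / fwd_d
        r_freq = pileup.rev[rows, minor_idx] / rev_d
        c_freq = minor_comb / (fwd_d + rev_d)
    hit = usable & (minor_comb > 0) & (f_freq >= min_minor_freq) & (r_freq >= min_minor_freq)
    calls = []
    for p in np.flatnonzero(hit):
        calls.append(
            HeteroplasmyCall(
                individual_id=pileup.individual_id,
                position=int(p) + 1,
                major=BASES[major_idx[p]],
                minor=BASES[minor_idx[p]],
                fwd_freq=float(f_freq[p]),
                rev_freq=float(r_freq[p]),
                combined_freq=float(c_freq[p]),
            )
        )
    return calls


def burden(calls, usable: set[int], individual_id: str | None = None) -> BurdenRecord:
    """Heteroplasmies per usable site for one individual."""
    calls = list(calls)
    stray = [c.position for c in calls if c.position not in usable]
    if stray:
        raise ConsistencyError(f"calls at non-usable positions: {sorted(stray)}")
    if individual_id is None:
        individual_id = calls[0].individual_id if calls else ""
    n_usable = len(usable)
    hpui = len(calls) / n_usable if n_usable > 0 else None
    return BurdenRecord(
        individual_id=individual_id,
        count=len(calls),
        usable_sites=n_usable,
        hpui=hpui,
    )


def sharing_spectrum(all_calls, individual_ids=None) -> SharingSpectrum:
    """How widely each heteroplasmic allele is shared across the cohort.

    ``individual_ids``, when given, fixes the population for the
    per-individual histogram so zero-call individuals are represented.
    """
    all_calls = list(all_calls)
    frame = pd.DataFrame(
        {
            "individual_id": [c.individual_id for c in all_calls],
            "position": [c.position for c in all_calls],
            "minor": [c.minor for c in all_calls],
        }
    )
    if frame.empty:
        carriers = pd.Series(dtype=int)
        per_ind = pd.Series(dtype=int)
    else:
        carriers = (
            frame.drop_duplicates()
            .groupby(["position", "minor"])
            .size()
            .sort_index()
        )
        per_ind = frame.groupby("individual_id").size()
    if individual_ids is not None:
        per_ind = per_ind.reindex(list(individual_ids), fill_value=0)
    per_ind.name = "heteroplasmy_count"
    carriers.name = "carriers"
    return SharingSpectrum(carriers=carriers, per_individual=per_ind)


def compare_burden(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two HPUI samples.

    Uses the tie-corrected normal approximation with continuity
    correction; for two small tie-free samples (both n ≤ 10) the exact
    null distribution is enumerated instead.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputContractError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    exact_ok = a.size <= 10 and b.size <= 10 and np.unique(pooled).size == pooled.size
    method = "exact" if exact_ok else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)
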