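"""Synthetic mtDNA cohort generator with known ground truth.

Every downstream stage of the pipeline (consensus calling, haplogroup
classification, heteroplasmy detection, association testing) is
testable against this module's output because the generator records the
truth it samples from: each individual's haplogroup, full variant set,
injected heteroplasmies and phenotype scores.

What is emulated
----------------
* a circular reference genome (~16.6 kb for a realistic run, smaller
  for demos) with uniform base composition;
* a shallow haplogroup tree whose major clades each cover a
  non-negligible share of the cohort;
* per-individual consensus variants: the clade-defining variants on the
  root-to-leaf path plus Poisson-distributed private variants, so
  realized variant counts land in the low tens;
* heteroplasmies at 1–10% minor-allele frequency, a little over one per
  individual on average;
* strand-specific sequencing depth around 1500× per strand drawn from a
  negative binomial, so the 10×/500× coverage gates are actually
  exercised;
* base errors at ≤0.1% (the residual error rate after PHRED-30
  filtering upstream of this pipeline's entry point);
* phenotypes: binary case/control status, 0–4 ordinal symptom
  frequency/severity scores, and 0–16 distress = frequency × severity,
  with configurable additive haplogroup/variant effects applied to the
  latent scores before discretization.

Reads, alignment, duplicates, NUMTs, indels and quality trimming are
upstream of the pipeline's entry point and are not simulated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError
from .genome import (
    BASES,
    BASE_INDEX,
    ReferenceGenome,
    parse_variant_token,
)
from .haplogroup import HaplogroupNode, HaplogroupTree, cumulative_variants
from .pileup import StrandPileup

_MAJOR_NAMES = "HUTKJVWXABCDEFGILMNR"
_SITES = ("Miami", "SaltLakeCity", "Boston", "NewYork", "Sierra")
_DEFAULT_SYMPTOMS = ("joint_pain", "bloating", "fatigue", "light_sensitivity")
_LATENT_MEAN = 1.5  # latent mean of the 0-4 frequency/severity grid
_LATENT_SD = 1.0


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic cohort; defaults emulate the study conditions.

    ``depth_mean`` is the per-strand mean coverage and
    ``depth_dispersion`` the negative-binomial size parameter (larger =
    closer to Poisson); the defaults give a realized depth spread close
    to the ~1500 ± 490 regime of deep mtDNA amplicon sequencing.
    ``het_rate`` is the expected number of heteroplasmies per
    individual, with per-site minor frequencies uniform on
    ``het_freq_range``. ``strand_bias`` multiplies the minor-allele
    frequency on the reverse strand only (0 creates single-strand
    artifacts for exercising double-strand validation).
    """

    n_cases: int = 193
    n_controls: int = 196
    depth_mean: float = 1500.0
    depth_dispersion: float = 9.4
    error_rate: float = 0.001
    het_rate: float = 1.35
    het_freq_range: tuple[float, float] = (0.01, 0.10)
    private_variant_rate: float = 3.0
    strand_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.het_freq_range
        if self.n_cases < 1 or self.n_controls < 1:
            raise InvalidParameterError("cohort sizes must be positive")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise InvalidParameterError("depth parameters must be positive")
        if not 0.0 <= self.error_rate <= 0.01:
            raise InvalidParameterError("error_rate must be in [0, 0.01]")
        if self.het_rate < 0:
            raise InvalidParameterError("het_rate must be nonnegative")
        if not 0.0 < lo <= hi <= 0.5:
            raise InvalidParameterError(
                "het_freq_range must satisfy 0 < low <= high <= 0.5"
            )
        if self.strand_bias < 0:
            raise InvalidParameterError("strand_bias must be nonnegative")


@dataclass(frozen=True)
class Effect:
    """An additive shift of a phenotype's latent score for carriers.

    ``target`` is either a haplogroup node name (carriers: individuals
    assigned to that node or any of its descendants) or a variant token
    such as ``"1234G"`` (carriers: individuals whose variant set
    contains it). ``phenotype`` names a generated symptom column, e.g.
    ``joint_pain_severity``. A shift on a ``*_distress`` phenotype is
    split equally between the frequency and severity latents so that
    the expected product moves by approximately ``size``.
    """

    target: str
    phenotype: str
    size: float


@dataclass(frozen=True)
class IndividualTruth:
    individual_id: str
    status: str  # "case" | "control"
    sex: str     # "F" | "M"
    age: int
    site: str
    haplogroup: str
    variants: frozenset[tuple[int, str]]
    heteroplasmies: tuple[tuple[int, str, float], ...]
    phenotypes: dict[str, float]


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, one record per individual."""

    individuals: list[IndividualTruth]
    effects: tuple[Effect, ...] = ()

    def phenotype_frame(self) -> pd.DataFrame:
        rows = []
        for ind in self.individuals:
            row = {
                "individual_id": ind.individual_id,
                "status": ind.status,
                "sex": ind.sex,
                "age": ind.age,
                "site": ind.site,
            }
            row.update(ind.phenotypes)
            rows.append(row)
        return pd.DataFrame(rows).set_index("individual_id")

    def ids(self) -> list[str]:
        return [ind.individual_id for ind in self.individuals]


def simulate_reference(length: int, seed: int, name: str = "chrM") -> ReferenceGenome:
    """Uniform-composition random circular reference of the given length."""
    if length < 1000:
        raise InvalidParameterError(f"reference length {length} below minimum 1000")
    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    return ReferenceGenome(name=name, sequence=seq)


def _chain_names(major: str, depth: int) -> list[str]:
    # H -> H1 -> H1a -> H1a1 ... alternating digit/letter refinements
    names = [major]
    for level in range(1, depth):
        suffix = "1" if level % 2 == 1 else "a"
        names.append(names[-1] + suffix)
    return names


def simulate_haplogroup_tree(
    n_major: int,
    depth: int,
    variants_per_branch: int,
    reference: ReferenceGenome,
    seed: int,
) -> HaplogroupTree:
    """Random tree: ``n_major`` root children, each a chain of ``depth`` nodes.

    Every branch carries ``variants_per_branch`` defining variants at
    globally unique positions, so no position recurs along any
    root-to-leaf path (and clade variant sets are pairwise disjoint).
    """
    if n_major < 2:
        raise InvalidParameterError("n_major must be at least 2")
    if depth < 1:
        raise InvalidParameterError("depth must be at least 1")
    if variants_per_branch < 1:
        raise InvalidParameterError("variants_per_branch must be at least 1")
    if n_major > len(_MAJOR_NAMES):
        raise InvalidParameterError(f"n_major must be <= {len(_MAJOR_NAMES)}")
    total = n_major * depth * variants_per_branch
    if total > reference.length:
        raise InvalidParameterError(
            f"cannot place {total} branch variants on a {reference.length} bp reference"
        )
    rng = np.random.default_rng(seed)
    positions = rng.choice(reference.length, size=total, replace=False) + 1
    pos_iter = iter(positions.tolist())
    root = "rCRS"
    nodes = {root: HaplogroupNode(name=root, parent=None, variants=frozenset())}
    for major in _MAJOR_NAMES[:n_major]:
        parent = root
        for name in _chain_names(major, depth):
            branch = []
            for _ in range(variants_per_branch):
                pos = next(pos_iter)
                alt = _random_alt(rng, reference.base(pos))
                branch.append((pos, alt))
            nodes[name] = HaplogroupNode(
                name=name, parent=parent, variants=frozenset(branch)
            )
            parent = name
    return HaplogroupTree(nodes=nodes, root=root, major_overrides={})


def _random_alt(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in BASES if b != ref_base]
    return choices[int(rng.integers(3))]


def _distress_latent_shift(size: float) -> float:
    # equal shift d on both latents moving E[f*s] by ~size:
    # (mu+d)^2 - mu^2 = size  =>  d = sqrt(mu^2 + size) - mu
    mu = _LATENT_MEAN
    return float(np.sqrt(max(mu * mu + size, 0.0)) - mu)


def _validate_effects(effects, tree: HaplogroupTree, symptoms) -> None:
    phenotype_names = set()
    for s in symptoms:
        phenotype_names |= {f"{s}_frequency", f"{s}_severity", f"{s}_distress"}
    for eff in effects:
        if eff.phenotype not in phenotype_names:
            raise ConfigurationError(
                f"effect names unknown phenotype {eff.phenotype!r}"
            )
        if eff.target not in tree.nodes:
            try:
                parse_variant_token(eff.target)
            except Exception:
                raise ConfigurationError(
                    f"effect target {eff.target!r} is neither a tree node nor "
                    "a variant token"
                ) from None


def _is_carrier(ind_leaf: str, ind_variants: dict[int, str],
                tree: HaplogroupTree, target: str) -> bool:
    if target in tree.nodes:
        return target in tree.path_from_root(ind_leaf)
    pos, allele = parse_variant_token(target)
    return ind_variants.get(pos) == allele


def simulate_cohort(
    tree: HaplogroupTree,
    reference: ReferenceGenome,
    params: SimulationParams,
    effects: tuple[Effect, ...] = (),
    seed: int | None = None,
    symptoms: tuple[str, ...] = _DEFAULT_SYMPTOMS,
) -> CohortTruth:
    """Sample a cohort with known haplogroups, variants, heteroplasmies and phenotypes.

    Each individual is assigned a uniformly random leaf of the tree;
    their variant set is the leaf's cumulative variants plus
    Poisson-distributed private variants at unused positions.
    Symptom frequency and severity are discretized latent normals on
    the 0–4 grid (distress = frequency × severity, on 0–16); effects
    shift carriers' latent scores before discretization. Controls are
    matched to cases marginally: the first ``min(n_cases, n_controls)``
    controls copy a case's sex and age within ±5 years.
    """
    if seed is None:
        seed = params.seed
    effects = tuple(effects)
    _validate_effects(effects, tree, symptoms)
    rng = np.random.default_rng(seed)
    tree_positions = {
        pos for node in tree.nodes.values() for pos, _ in node.variants
    }
    leaf_names = tree.leaves()
    lo, hi = params.het_freq_range

    case_demo: list[tuple[str, int]] = []
    individuals: list[IndividualTruth] = []
    statuses = ["case"] * params.n_cases + ["control"] * params.n_controls
    n_ctrl_seen = 0
    for i, status in enumerate(statuses):
        ind_id = f"{'case' if status == 'case' else 'ctrl'}_{i:04d}"
        if status == "case":
            sex = "F" if rng.random() < 0.7 else "M"
            age = int(rng.integers(21, 76))
            case_demo.append((sex, age))
        else:
            if n_ctrl_seen < len(case_demo):
                sex, matched_age = case_demo[n_ctrl_seen]
                age = int(np.clip(matched_age + rng.integers(-5, 6), 21, 75))
            else:
                sex = "F" if rng.random() < 0.7 else "M"
                age = int(rng.integers(21, 76))
            n_ctrl_seen += 1
        site = _SITES[int(rng.integers(len(_SITES)))]

        leaf = leaf_names[int(rng.integers(len(leaf_names)))]
        variants = dict(cumulative_variants(tree, leaf))
        n_private = int(rng.poisson(params.private_variant_rate))
        placed = 0
        while placed < n_private:
            pos = int(rng.integers(1, reference.length + 1))
            if pos in tree_positions or pos in variants:
                continue
            variants[pos] = _random_alt(rng, reference.base(pos))
            placed += 1

        n_het = int(rng.poisson(params.het_rate))
        het_list: list[tuple[int, str, float]] = []
        het_positions: set[int] = set()
        while len(het_list) < n_het:
            pos = int(rng.integers(1, reference.length + 1))
            if pos in variants or pos in het_positions:
                continue
            consensus_base = reference.base(pos)
            minor = _random_alt(rng, consensus_base)
            freq = float(rng.uniform(lo, hi))
            het_list.append((pos, minor, freq))
            het_positions.add(pos)

        phenotypes: dict[str, float] = {}
        for s in symptoms:
            shift_f = shift_s = 0.0
            for eff in effects:
                if not _is_carrier(leaf, variants, tree, eff.target):
                    continue
                if eff.phenotype == f"{s}_frequency":
                    shift_f += eff.size
                elif eff.phenotype == f"{s}_severity":
                    shift_s += eff.size
                elif eff.phenotype == f"{s}_distress":
                    d = _distress_latent_shift(eff.size)
                    shift_f += d
                    shift_s += d
            freq_score = int(
                np.clip(np.rint(rng.normal(_LATENT_MEAN + shift_f, _LATENT_SD)), 0, 4)
            )
            sev_score = int(
                np.clip(np.rint(rng.normal(_LATENT_MEAN + shift_s, _LATENT_SD)), 0, 4)
            )
            phenotypes[f"{s}_frequency"] = float(freq_score)
            phenotypes[f"{s}_severity"] = float(sev_score)
            phenotypes[f"{s}_distress"] = float(freq_score * sev_score)

        individuals.append(
            IndividualTruth(
                individual_id=ind_id,
                status=status,
                sex=sex,
                age=age,
                site=site,
                haplogroup=leaf,
                variants=frozenset(variants.items()),
                heteroplasmies=tuple(het_list),
                phenotypes=phenotypes,
            )
        )
    return CohortTruth(individuals=individuals, effects=effects)


def simulate_strand_counts(
    individual: IndividualTruth,
    reference: ReferenceGenome,
    params: SimulationParams,
    rng: np.random.Generator,
) -> StrandPileup:
    """Draw one individual's per-strand base-count table.

    Per strand, depth at each position is negative binomial with mean
    ``depth_mean``; sequencing errors hit at ``error_rate`` and are
    spread uniformly over the three non-consensus bases; at
    heteroplasmic sites the minor-allele count is binomial around the
    true frequency on each strand independently (the reverse-strand
    frequency is multiplied by ``strand_bias``).
    """
    L = reference.length
    codes = np.frombuffer(reference.sequence.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    codes = lut[codes]
    for pos, allele in individual.variants:
        codes[pos - 1] = BASE_INDEX[allele]

    # base indices of the three non-consensus alleles for each consensus code
    others = np.array([[b for b in range(4) if b != c] for c in range(4)])
    k = params.depth_dispersion
    p_nb = k / (k + params.depth_mean)

    strands = []
    for strand in ("fwd", "rev"):
        depth = rng.negative_binomial(k, p_nb, size=L)
        errors = (
            rng.binomial(depth, params.error_rate)
            if params.error_rate > 0
            else np.zeros(L, dtype=np.int64)
        )
        counts = np.zeros((L, 4), dtype=np.int64)
        if errors.any():
            slots = rng.multinomial(errors, [1 / 3] * 3)
            cols = others[codes]
            np.add.at(counts, (np.repeat(np.arange(L), 3), cols.ravel()), slots.ravel())
        minor_total = np.zeros(L, dtype=np.int64)
        for pos, minor, freq in individual.heteroplasmies:
            f = freq if strand == "fwd" else min(freq * params.strand_bias, 1.0)
            room = int(depth[pos - 1] - errors[pos - 1])
            m = min(int(rng.binomial(depth[pos - 1], f)), max(room, 0))
            counts[pos - 1, BASE_INDEX[minor]] += m
            minor_total[pos - 1] += m
        counts[np.arange(L), codes] += depth - errors - minor_total
        strands.append(counts)
    return StrandPileup(
        individual_id=individual.individual_id,
        reference_name=reference.name,
        fwd=strands[0],
        rev=strands[1],
    )


def _pileup_lines(counts: np.ndarray, reference: ReferenceGenome,
                  match_symbol: str, letter_case: str):
    ref_seq = reference.sequence
    for i in range(counts.shape[0]):
        row = counts[i]
        depth = int(row.sum())
        if depth == 0:
            continue
        ref_base = ref_seq[i]
        parts = []
        for b, n in zip(BASES, row):
            if n == 0:
                continue
            if b == ref_base:
                parts.append(match_symbol * int(n))
            else:
                sym = b if letter_case == "upper" else b.lower()
                parts.append(sym * int(n))
        bases = "".join(parts)
        yield f"{reference.name}\t{i + 1}\t{ref_base}\t{depth}\t{bases}\t{'I' * depth}\n"


def emit_pileups(
    truth: CohortTruth,
    reference: ReferenceGenome,
    params: SimulationParams,
    out_dir,
    seed: int | None = None,
) -> pd.DataFrame:
    """Write a forward and a reverse pileup file per individual.

    Returns the manifest (individual_id, forward, reverse paths) and
    writes it to ``manifest.tsv`` in ``out_dir``. Output is
    deterministic for a fixed (truth, params, seed).
    """
    if seed is None:
        seed = params.seed
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for ind in truth.individuals:
        sp = simulate_strand_counts(ind, reference, params, rng)
        fwd_path = os.path.join(out_dir, f"{ind.individual_id}.fwd.pileup")
        rev_path = os.path.join(out_dir, f"{ind.individual_id}.rev.pileup")
        with open(fwd_path, "w") as fh:
            fh.writelines(_pileup_lines(sp.fwd, reference, ".", "upper"))
        with open(rev_path, "w") as fh:
            fh.writelines(_pileup_lines(sp.rev, reference, ",", "lower"))
        rows.append(
            {
                "individual_id": ind.individual_id,
                "forward": os.path.basename(fwd_path),
                "reverse": os.path.basename(rev_path),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest


def write_truth_tables(truth: CohortTruth, out_dir) -> None:
    """Dump the generator's ground truth as TSV tables."""
    os.makedirs(out_dir, exist_ok=True)
    inds = pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "status": i.status,
                "sex": i.sex,
                "age": i.age,
                "site": i.site,
                "haplogroup": i.haplogroup,
            }
            for i in truth.individuals
        ]
    )
    inds.to_csv(os.path.join(out_dir, "truth_individuals.tsv"), sep="\t", index=False)
    variants = pd.DataFrame(
        [
            {"individual_id": i.individual_id, "position": pos, "allele": allele}
            for i in truth.individuals
            for pos, allele in sorted(i.variants)
        ],
        columns=["individual_id", "position", "allele"],
    )
    variants.to_csv(os.path.join(out_dir, "truth_variants.tsv"), sep="\t", index=False)
    hets = pd.DataFrame(
        [
            {
                "individual_id": i.individual_id,
                "position": pos,
                "minor": minor,
                "frequency": freq,
            }
            for i in truth.individuals
            for pos, minor, freq in i.heteroplasmies
        ],
        columns=["individual_id", "position", "minor", "frequency"],
    )
    hets.to_csv(os.path.join(out_dir, "truth_heteroplasmies.tsv"), sep="\t", index=False)
    truth.phenotype_frame().to_csv(os.path.join(out_dir, "phenotypes.tsv"), sep="\t")
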