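"""End-to-end orchestration: pileups → consensus → haplogroups →
heteroplasmy → associations → report.

Each stage reads its inputs from disk and writes plain-text TSV/FASTA
artifacts into the configured output directory, so stages are
independently invocable (and re-runnable from cached intermediates)
both from Python and from the command line. All randomness (the Monte
Carlo branch of the overall haplogroup test) flows from the single
configured seed, making a run fully deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import association as assoc
from . import consensus as cons
from . import heteroplasmy as het
from . import haplogroup as hg
from . import pileup as pio
from . import simulate as sim
from .errors import ConfigurationError
from .genome import read_reference_fasta, write_reference_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed of one pipeline run."""

    reference: str
    manifest: str
    tree: str
    phenotypes: str
    out_dir: str
    pathogenic_table: str | None = None
    score_table: str | None = None
    consensus_min_depth: int = 10
    het_min_depth: int = 500
    het_min_freq: float = 0.01
    min_maf: float = 0.05
    max_missing: float = 0.10
    clade_min_freq: float = 0.05
    fdr: float = 0.05
    stratify_by_sex: bool = False
    seed: int = 0

    def validate(self) -> None:
        for label in ("reference", "manifest", "tree", "phenotypes"):
            path = getattr(self, label)
            if not os.path.exists(path):
                raise ConfigurationError(f"{label} path does not exist: {path}")
        for label in ("pathogenic_table", "score_table"):
            path = getattr(self, label)
            if path is not None and not os.path.exists(path):
                raise ConfigurationError(f"{label} path does not exist: {path}")
        if self.consensus_min_depth < 1 or self.het_min_depth < 1:
            raise ConfigurationError("depth thresholds must be positive")
        if not 0 < self.het_min_freq <= 0.5:
            raise ConfigurationError("het_min_freq must be in (0, 0.5]")
        if not 0 <= self.min_maf <= 0.5:
            raise ConfigurationError("min_maf must be in [0, 0.5]")
        for label in ("max_missing", "clade_min_freq", "fdr"):
            if not 0 <= getattr(self, label) <= 1:
                raise ConfigurationError(f"{label} must be in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    elapsed: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "counts": self.counts,
                    "warnings": self.warnings,
                    "elapsed_seconds": {k: round(v, 3) for k, v in self.elapsed.items()},
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")


def _read_manifest(config: PipelineConfig) -> pd.DataFrame:
    manifest = pd.read_csv(config.manifest, sep="\t", dtype=str)
    base = os.path.dirname(os.path.abspath(config.manifest))
    for col in ("forward", "reverse"):
        manifest[col] = manifest[col].map(
            lambda p: p if os.path.isabs(p) else os.path.join(base, p)
        )
    return manifest


def _iter_pileups(config: PipelineConfig, reference):
    for row in _read_manifest(config).itertuples():
        yield pio.read_strand_pileups(
            row.forward, row.reverse, reference, individual_id=row.individual_id
        )


def run_calling_stage(config: PipelineConfig) -> None:
    """Consensus + heteroplasmy calling for every individual in the manifest.

    Writes consensus.fasta, variants.tsv, cohort.hsd, het_calls.tsv and
    burden.tsv into the output directory.
    """
    reference = read_reference_fasta(config.reference)
    os.makedirs(config.out_dir, exist_ok=True)
    profiles, variant_sets = [], []
    call_rows, burden_rows = [], []
    for sp in _iter_pileups(config, reference):
        profile = cons.call_consensus(sp, min_strand_depth=config.consensus_min_depth)
        profiles.append(profile)
        variant_sets.append(cons.extract_variants(profile, reference))
        usable = het.usable_sites(sp, min_strand_depth=config.het_min_depth)
        calls = het.call_heteroplasmies(
            sp,
            min_minor_freq=config.het_min_freq,
            min_strand_depth=config.het_min_depth,
        )
        record = het.burden(calls, usable, individual_id=sp.individual_id)
        burden_rows.append(
            {
                "individual_id": record.individual_id,
                "count": record.count,
                "usable_sites": record.usable_sites,
                "hpui": record.hpui if record.hpui is not None else np.nan,
            }
        )
        for c in calls:
            call_rows.append(
                {
                    "individual_id": c.individual_id,
                    "position": c.position,
                    "major": c.major,
                    "minor": c.minor,
                    "fwd_freq": c.fwd_freq,
                    "rev_freq": c.rev_freq,
                    "combined_freq": c.combined_freq,
                }
            )
    pio.write_consensus_fasta(profiles, os.path.join(config.out_dir, "consensus.fasta"))
    pio.write_hsd(
        variant_sets, f"1-{reference.length}", os.path.join(config.out_dir, "cohort.hsd")
    )
    pd.DataFrame(
        [
            {"individual_id": vs.individual_id, "position": pos, "allele": allele}
            for vs in variant_sets
            for pos, allele in sorted(vs.variants)
        ],
        columns=["individual_id", "position", "allele"],
    ).to_csv(os.path.join(config.out_dir, "variants.tsv"), sep="\t", index=False)
    pd.DataFrame(
        call_rows,
        columns=[
            "individual_id", "position", "major", "minor",
            "fwd_freq", "rev_freq", "combined_freq",
        ],
    ).to_csv(os.path.join(config.out_dir, "het_calls.tsv"), sep="\t", index=False)
    pd.DataFrame(burden_rows).to_csv(
        os.path.join(config.out_dir, "burden.tsv"), sep="\t", index=False
    )


def _load_variant_sets(config: PipelineConfig) -> list[cons.VariantSet]:
    table = pd.read_csv(
        os.path.join(config.out_dir, "variants.tsv"),
        sep="\t",
        dtype={"individual_id": str, "position": int, "allele": str},
    )
    ids = [r.individual_id for r in _read_manifest(config).itertuples()]
    grouped = {
        ind: frozenset(zip(g["position"], g["allele"]))
        for ind, g in table.groupby("individual_id")
    }
    return [
        cons.VariantSet(individual_id=i, variants=grouped.get(i, frozenset()))
        for i in ids
    ]


def run_classify_stage(config: PipelineConfig) -> pd.DataFrame:
    """Classify every individual from cached variants.tsv; write assignments.tsv."""
    tree = hg.read_tree_json(config.tree)
    rows = []
    for vs in _load_variant_sets(config):
        a = hg.classify(vs, tree)
        rows.append(
            {
                "individual_id": a.individual_id,
                "haplogroup": a.haplogroup,
                "score": a.score,
                "major_clade": a.major_clade,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(os.path.join(config.out_dir, "assignments.tsv"), sep="\t", index=False)
    return out


def _covariate_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    cov = pd.DataFrame(index=pheno.index)
    cov["sex"] = (pheno["sex"] == "F").astype(float)
    cov["age"] = pheno["age"].astype(float)
    sites = sorted(pheno["site"].unique())
    for s in sites[1:]:  # first site is the baseline
        cov[f"site_{s}"] = (pheno["site"] == s).astype(float)
    return cov


def _symptom_columns(pheno: pd.DataFrame) -> list[str]:
    reserved = {"status", "sex", "age", "site"}
    return [c for c in pheno.columns if c not in reserved]


def run_association_stage(config: PipelineConfig) -> RunReport:
    """All cohort statistics from cached intermediates.

    Writes haplogroup_disease.tsv, haplogroup_symptoms.tsv,
    snp_disease.tsv, snp_symptoms.tsv, heteroplasmy_tests.json and
    (when score tables are configured) pathogenic_hits.tsv plus the KS
    burden comparison; returns a RunReport with per-stage counts.
    """
    report = RunReport()
    reference = read_reference_fasta(config.reference)
    pheno = pd.read_csv(config.phenotypes, sep="\t", index_col="individual_id")
    assignments = pd.read_csv(
        os.path.join(config.out_dir, "assignments.tsv"), sep="\t", index_col="individual_id"
    )
    ids = assignments.index.tolist()
    pheno = pheno.loc[ids]
    covariates = _covariate_frame(pheno)
    status = (pheno["status"] == "case").astype(float)

    # --- haplogroup vs disease: per-clade Fisher + overall distribution
    clade = assignments["major_clade"]
    rows = []
    for name in sorted(clade.unique()):
        in_clade = clade == name
        a = int((in_clade & (status == 1)).sum())
        b = int((in_clade & (status == 0)).sum())
        c = int(((~in_clade) & (status == 1)).sum())
        d = int(((~in_clade) & (status == 0)).sum())
        res = assoc.fisher_2x2(assoc.ContingencyTable2x2(a, b, c, d))
        rows.append(
            {
                "haplogroup": name, "case": a, "control": b,
                "p": res.p, "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
            }
        )
    hg_disease = pd.DataFrame(rows)
    if not hg_disease.empty:
        hg_disease["q"] = assoc.bh_adjust(hg_disease["p"])
    hg_disease.to_csv(
        os.path.join(config.out_dir, "haplogroup_disease.tsv"), sep="\t", index=False
    )
    counts_rx2 = (
        pd.crosstab(clade, status).reindex(columns=[1.0, 0.0], fill_value=0).to_numpy()
    )
    overall = assoc.overall_distribution_test(counts_rx2, seed=config.seed)
    report.counts["haplogroup_disease_tests"] = len(hg_disease)

    # --- haplogroup indicators vs symptoms
    indicators = hg.haplogroup_covariates(
        [
            hg.HaplogroupAssignment(i, r.haplogroup, r.score, r.major_clade)
            for i, r in assignments.iterrows()
        ],
        min_freq=config.clade_min_freq,
    )
    symptoms = pheno[_symptom_columns(pheno)]
    hg_symptoms = assoc.haplogroup_symptom_scan(
        indicators, symptoms, covariates, fdr=config.fdr
    )
    hg_symptoms.to_csv(
        os.path.join(config.out_dir, "haplogroup_symptoms.tsv"), sep="\t", index=False
    )

    # --- single-marker scans from the consensus genotype matrix
    profiles = [
        cons.profile_from_sequence(rec.id, str(rec.seq), reference.name)
        for rec in SeqIO.parse(os.path.join(config.out_dir, "consensus.fasta"), "fasta")
    ]
    genotypes = assoc.genotype_matrix(profiles, reference).loc[ids]
    filtered = assoc.filter_sites(
        genotypes, max_missing=config.max_missing, min_maf=config.min_maf
    )
    report.counts["sites_total"] = genotypes.shape[1]
    report.counts["sites_tested"] = filtered.shape[1]
    snp_disease = assoc.marker_phenotype_scan(
        filtered, pd.DataFrame({"status": status}), covariates, fdr=config.fdr
    )
    snp_disease.to_csv(
        os.path.join(config.out_dir, "snp_disease.tsv"), sep="\t", index=False
    )
    snp_symptoms = assoc.marker_phenotype_scan(
        filtered, symptoms, covariates, fdr=config.fdr
    )
    snp_symptoms.to_csv(
        os.path.join(config.out_dir, "snp_symptoms.tsv"), sep="\t", index=False
    )
    if config.stratify_by_sex:
        def per_stratum(idx):
            sub = assoc.filter_sites(
                genotypes.loc[idx],
                max_missing=config.max_missing,
                min_maf=config.min_maf,
            )
            return assoc.marker_phenotype_scan(
                sub,
                pd.DataFrame({"status": status.loc[idx]}),
                covariates.loc[idx].drop(columns=["sex"]),
                fdr=config.fdr,
            )

        try:
            strata = assoc.stratified_run(pheno["sex"], per_stratum)
            for level, table in strata.items():
                table.to_csv(
                    os.path.join(config.out_dir, f"snp_disease_{level}.tsv"),
                    sep="\t",
                    index=False,
                )
        except Exception as exc:
            report.warnings.append(f"sex-stratified scan skipped: {exc}")

    # --- heteroplasmy burden comparison
    burden_tab = pd.read_csv(
        os.path.join(config.out_dir, "burden.tsv"), sep="\t", index_col="individual_id"
    ).loc[ids]
    hpui = burden_tab["hpui"].dropna()
    case_ids = status.index[status == 1]
    ctrl_ids = status.index[status == 0]
    het_tests = {}
    if len(hpui.reindex(case_ids).dropna()) and len(hpui.reindex(ctrl_ids).dropna()):
        het_tests["hpui_case_control_p"] = het.compare_burden(
            hpui.reindex(case_ids).dropna(), hpui.reindex(ctrl_ids).dropna()
        )
    calls_tab = pd.read_csv(os.path.join(config.out_dir, "het_calls.tsv"), sep="\t")
    per_ind = calls_tab.groupby("individual_id").size().reindex(ids, fill_value=0)
    het_tests["mean_heteroplasmies_per_individual"] = float(per_ind.mean())
    if not calls_tab.empty:
        carriers = calls_tab.groupby(["position", "minor"]).size()
        het_tests["distinct_heteroplasmies"] = int(len(carriers))
        het_tests["mean_carriers_per_heteroplasmy"] = float(carriers.mean())
        carriers.rename("carriers").reset_index().to_csv(
            os.path.join(config.out_dir, "sharing_spectrum.tsv"), sep="\t", index=False
        )
    het_tests["overall_haplogroup_distribution_p"] = overall.p
    with open(os.path.join(config.out_dir, "heteroplasmy_tests.json"), "w") as fh:
        json.dump(het_tests, fh, indent=1, sort_keys=True)
        fh.write("\n")

    # --- pathogenic screening and pathogenicity burden
    if config.pathogenic_table is not None:
        table = cons.read_pathogenic_table(config.pathogenic_table)
        hits = []
        for vs in _load_variant_sets(config):
            matched = cons.screen_pathogenic(vs, table)
            for r in matched.itertuples():
                hits.append(
                    {
                        "individual_id": vs.individual_id,
                        "position": r.position,
                        "allele": r.allele,
                        "disease": r.disease,
                    }
                )
        pd.DataFrame(
            hits, columns=["individual_id", "position", "allele", "disease"]
        ).to_csv(os.path.join(config.out_dir, "pathogenic_hits.tsv"), sep="\t", index=False)
        report.counts["pathogenic_hits"] = len(hits)
    if config.score_table is not None:
        scores = pd.read_csv(config.score_table, sep="\t")
        averages = {
            vs.individual_id: cons.average_pathogenicity(vs, scores)
            for vs in _load_variant_sets(config)
        }
        case_scores = [averages[i] for i in case_ids if averages.get(i) is not None]
        ctrl_scores = [averages[i] for i in ctrl_ids if averages.get(i) is not None]
        if case_scores and ctrl_scores:
            stat, p = assoc.pathogenicity_burden_test(case_scores, ctrl_scores)
            with open(os.path.join(config.out_dir, "pathogenicity_ks.json"), "w") as fh:
                json.dump({"ks_statistic": stat, "p": p}, fh, indent=1)
                fh.write("\n")

    report.counts["individuals"] = len(ids)
    report.counts["heteroplasmy_calls"] = int(len(calls_tab))
    report.counts["symptom_tests_run"] = len(hg_symptoms) + len(snp_symptoms)
    report.counts["symptom_tests_flagged"] = int(
        hg_symptoms["significant"].sum() + snp_symptoms["significant"].sum()
    ) if len(hg_symptoms) or len(snp_symptoms) else 0
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage in dependency order and write run_report.json."""
    config.validate()
    report = RunReport()
    stages = [
        ("calling", run_calling_stage),
        ("classify", run_classify_stage),
        ("association", run_association_stage),
    ]
    for name, fn in stages:
        t0 = time.monotonic()
        try:
            result = fn(config)
        except Exception as exc:
            raise type(exc)(f"stage {name!r} failed: {exc}") from exc
        report.elapsed[name] = time.monotonic() - t0
        if isinstance(result, RunReport):
            report.counts.update(result.counts)
            report.warnings.extend(result.warnings)
    variants = pd.read_csv(os.path.join(config.out_dir, "variants.tsv"), sep="\t")
    report.counts["consensus_variants"] = int(len(variants))
    report.write(os.path.join(config.out_dir, "run_report.json"))
    return report


def make_demo(out_dir, seed: int = 42) -> PipelineConfig:
    """Write a small, fully self-contained demo dataset and its config.

    ~40 individuals on a 2 kb reference with 5 major haplogroups. The
    first individual carries two sentinel heteroplasmies bracketing the
    calling threshold — one at 5% minor frequency (well above the 1%
    rule) and one at 0.2% (clearly below it) — so a demo run
    demonstrates both a positive call and a rejected sub-threshold
    signal.
    """
    os.makedirs(out_dir, exist_ok=True)
    reference = sim.simulate_reference(2000, seed=seed)
    tree = sim.simulate_haplogroup_tree(
        n_major=5, depth=2, variants_per_branch=3, reference=reference, seed=seed + 1
    )
    params = sim.SimulationParams(
        n_cases=20,
        n_controls=20,
        depth_mean=700.0,
        depth_dispersion=30.0,
        error_rate=0.001,
        het_rate=1.5,
        het_freq_range=(0.02, 0.10),
        private_variant_rate=3.0,
        seed=seed,
    )
    truth = sim.simulate_cohort(tree, reference, params, seed=seed)
    first = truth.individuals[0]
    taken = {pos for pos, _ in first.variants} | {
        pos for pos, _, _ in first.heteroplasmies
    }
    sentinels = []
    for pos in range(1, reference.length + 1):
        if pos not in taken:
            sentinels.append(pos)
            taken.add(pos)
        if len(sentinels) == 2:
            break
    above = (sentinels[0], _other_base(reference.base(sentinels[0])), 0.05)
    below = (sentinels[1], _other_base(reference.base(sentinels[1])), 0.002)
    truth.individuals[0] = dataclasses.replace(
        first, heteroplasmies=first.heteroplasmies + (above, below)
    )

    write_reference_fasta(reference, os.path.join(out_dir, "reference.fasta"))
    hg.write_tree_json(tree, os.path.join(out_dir, "tree.json"))
    sim.emit_pileups(truth, reference, params, os.path.join(out_dir, "pileups"), seed=seed)
    sim.write_truth_tables(truth, out_dir)
    config = PipelineConfig(
        reference=os.path.join(out_dir, "reference.fasta"),
        manifest=os.path.join(out_dir, "pileups", "manifest.tsv"),
        tree=os.path.join(out_dir, "tree.json"),
        phenotypes=os.path.join(out_dir, "phenotypes.tsv"),
        out_dir=os.path.join(out_dir, "results"),
        seed=seed,
    )
    config.to_json(os.path.join(out_dir, "config.json"))
    return config


def _other_base(ref_base: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
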