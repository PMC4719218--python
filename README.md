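# mitocohort

Strand-aware mitochondrial-genome analysis for case-control cohorts:
consensus calling, haplogroup classification, double-strand-validated
heteroplasmy detection, and association testing with FDR control — plus
a synthetic-cohort generator with known ground truth so every stage can
be validated end to end without access to raw patient data.

## Who this is for

Groups running deep amplicon sequencing of human mtDNA (hundreds to
thousands of × coverage per strand) in a case-control design, who need
to go from strand-specific `samtools mpileup` text files to:

* per-individual consensus sequences and variant sets vs the rCRS,
* haplogroup assignments and major-clade indicator covariates,
* heteroplasmy calls robust to strand artifacts, with per-individual
  burden normalized per usable site (HPUI),
* cohort statistics: per-haplogroup Fisher exact tests with exact
  conditional confidence intervals, covariate-adjusted single-marker
  regressions, Benjamini–Hochberg q-values, Wilcoxon and
  Kolmogorov–Smirnov group comparisons, and pathogenic-variant /
  pathogenicity-score screening against user-supplied tables.

## The statistics at the core

**Consensus.** At each position the called allele maximizes the
combined strand count; positions with per-strand depth < 10× are
missing. Variants are positions where the call differs from the
reference base.

**Heteroplasmy.** At positions with ≥ 500× on *each* strand, the
second-most-frequent allele is called heteroplasmic iff its frequency
is ≥ 1% on *each* strand independently (double-strand validation).
Burden for individual *i* is HPUI_i = (# calls)/(# usable sites), and
groups are compared with the Wilcoxon rank-sum test (tie-corrected
normal approximation with continuity correction).

**Haplogroups.** A clade's expected variants are the union along the
root-to-clade path (later branches override earlier alleles). The
assignment maximizes the symmetric concordance

    score(E, O) = ( |E∩O|/|E| + |E∩O|/|O| ) / 2

between expected set E and observed set O; ties go to the deeper clade.

**Association.** For a 2×2 haplogroup table the odds ratio is the
cross-product ratio ad/bc, the two-sided p sums hypergeometric
probabilities ≤ the observed table's, and the 95% CI inverts the
noncentral hypergeometric likelihood (alpha/2 per tail, matching
R's `fisher.test`). Phenotypes with > 2 values use linear regression,
binary ones logistic, with sex, age and collection site as covariates;
q-values are BH step-up within each phenotype's marker family.

## A worked example

```bash
python examples/05_association.py
```

prints, for the published 193-case / 196-control haplogroup counts:

```
haplogroup  OR      95% CI           p      q
T           0.47  0.22 - 0.96    0.03  0.66
H           1.30  0.85 - 2.00    0.21  0.98
J           1.23  0.47 - 3.27    0.67  0.98
M           2.04  0.11 - 121.07  0.62  0.98
```

Haplogroup T is nominally enriched in controls (a possible protective
effect), but the BH q-value across all 20 haplogroups is far above a
5% FDR, so the cohort shows no haplogroup–disease association. The same
script then plants a 3-point haplogroup effect on a 0–16 distress score
in a simulated cohort and shows the covariate-adjusted scan flagging
exactly the planted clade.

Other examples: `01` cohort simulation, `02` consensus recovery,
`03` classification, `04` heteroplasmy + HPUI, `06` the full pipeline
on a generated demo dataset (`mitocohort make-demo` / `run-all` do the
same from the shell).

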