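# Methods

## Input model and coordinates

The pipeline's entry point is a pair of SAMtools-mpileup text files per
individual — one from forward-strand reads, one from reverse-strand
reads — over a single circular reference. Read mapping, duplicate
removal, NUMT exclusion and quality trimming are upstream of this entry
point; the parser therefore accepts only the substitution dialect of
the read-bases column (`.`/`,` and `ACGTacgt`) and rejects indel,
read-boundary and deletion tokens loudly rather than skipping them.
Coordinates are 1-based and inclusive everywhere, matching pileup and
rCRS numbering; positions absent from a file are zero-coverage by
convention, and no wraparound arithmetic is needed because all
downstream logic is per-position.

## Consensus and variants

The consensus allele is the argmax of the combined (forward + reverse)
base counts, gated by a per-strand minimum depth (default 10×; the
strand rule is a coverage gate only, the argmax itself uses combined
counts). Ties at the argmax are left missing rather than resolved
arbitrarily: a 50/50 site at consensus scale is an unresolved mixture,
and the heteroplasmy caller is the appropriate instrument for it.
Variants are called positions differing from the reference; missing
positions contribute nothing. No hypervariable-position masking is
applied.

## Heteroplasmy calling

A site is usable when each strand has at least `min_strand_depth`
(default 500×) coverage. At usable sites the single largest minor
allele (by combined count) is evaluated; a call requires its frequency
to reach `min_minor_freq` (default 1%, inclusive — "at least" is read
literally) on each strand independently, with that strand's total
depth as denominator. One call per position at most: tri-allelic sites
yield only the largest minor. The double-strand rule is the caller's
defining feature; a signal confined to one strand — the signature of
amplification or alignment artifacts — is never called, which the test
suite asserts as a property using the generator's strand-bias knob.

Burden is heteroplasmies per usable site (HPUI), undefined (not zero)
for an individual with no usable sites. Group comparisons use the
Wilcoxon rank-sum test as the tie-corrected normal approximation with
continuity correction; for two tie-free samples of at most 10 the
exact permutation null is enumerated instead.

## Haplogroup classification

A clade's expected variant set is the union of branch-defining variants
along the root-to-clade path, with later branches overriding earlier
alleles at the same position (back-mutation semantics; a back-mutation
to the reference base itself cannot be encoded, which is acceptable for
the bundled synthetic trees where positions are globally unique).
Classification maximizes the symmetric mean of recall and precision
(a Kulczynski-type measure), defined as 1 when both sets are empty and
0 when exactly one is. This scoring rule is a deliberate, documented
replacement for proprietary classifier rankings: it is monotone in
overlap, penalizes both missing and extra variants, and is exactly
reproducible. Ties break toward the deeper clade, then lexicographic
name. Major clades are the leading alphabetic run of the node name
(so H2a1 → H while HV stays distinct from H), with an explicit
override map for trees whose naming deviates. Indicator covariates
include only clades at ≥ 5% cohort frequency, and an HSD export is
provided for cross-checking against external classifiers. All
positions weigh equally; no mutation-rate weighting is applied.

## Association layer

* **2×2 Fisher.** Two-sided p by probability-mass ordering (the
  dominant software convention). The reported odds ratio is the sample
  cross-product ratio ad/bc — undefined when a zero cell degenerates
  it — because that is what published cohort tables print; the
  conditional maximum-likelihood estimate is computed alongside. The
  95% CI inverts the noncentral hypergeometric likelihood with alpha/2
  per tail. The NCHG pmf, mean and tail sums are computed in log space
  directly over the (small) support, which stays numerically stable at
  the extreme odds values the root-finder visits.
* **Overall r×2 homogeneity.** Exact enumeration of all tables with
  the observed margins when the total count is ≤ 60 (configurable);
  otherwise Monte Carlo with ≥ 10⁵ Patefield draws, reporting the
  binomial standard error of the estimate.
* **BH.** Standard step-up with running minimum and cap at 1, returned
  in input order. FDR families follow the analysis design: the
  haplogroup–disease scan is one family over all haplogroups tested;
  symptom scans form one family per phenotype over the marker set, with
  no correction across (mutually dependent) phenotypes.
* **Single-marker tests.** Sites are filtered on missingness (≤ 10%)
  and cohort MAF (≥ 5%, computed among non-missing individuals, which
  necessarily removes singletons at realistic cohort sizes). Phenotypes
  with more than two distinct values get OLS, binary ones get
  maximum-likelihood logistic regression with the effect reported as an
  odds ratio; p-values are Wald tests on the allele coefficient, with
  sex, age and collection-site indicators as covariates. Degenerate
  fits — constant response, constant allele after subsetting, fewer
  than 10 complete observations, non-convergence or separation
  (detected by convergence flags and a |coefficient| > 15 guard) — are
  skipped with a logged warning rather than penalized or patched,
  keeping inference conventional and transparent.
* **Stratified runs** re-execute an arbitrary analysis closure within
  each stratum, so filters are recomputed per stratum; strata below 10
  individuals are skipped with a log entry.
* **Pathogenicity.** Known-pathogenic screening is an exact
  (position, allele) lookup against a user-supplied TSV. Per-individual
  pathogenicity burden is the mean score over the individual's
  variants (undefined, not zero, with no variants) and groups are
  compared with the two-sample KS test (asymptotic two-sided p).

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is
validated; its defaults emulate a deep-coverage human mtDNA
case-control study:

| parameter | default | rationale |
|---|---|---|
| cohort size | 193 cases / 196 controls | study-scale case-control design |
| per-strand depth | negative binomial, mean 1500, size 9.4 | deep amplicon coverage with overdispersion (realized spread ≈ ±490), so the 10×/500× gates actually trigger |
| base error rate | 0.1% | residual error after PHRED-30 filtering upstream |
| heteroplasmies/individual | Poisson(1.35) | a little over one per individual |
| minor frequency | uniform on (1%, 10%) | the low-frequency regime of interest; the uniform shape is a stand-in, not an inference |
| private variants | Poisson(3) per individual | pushes realized variant counts into the low-to-mid twenties with a 20-variant leaf path, and makes singleton exclusion exercisable |
| phenotype latents | Normal(1.5, 1) discretized to 0–4 | symmetric occupancy of the ordinal grid |

Haplogroup trees are n chains of named clades hanging off the root,
each branch carrying a fixed number of defining variants at globally
unique positions (hence disjoint clades and no within-path reuse).
Individuals draw a uniform leaf; heteroplasmy sites avoid the
individual's variant positions so truth frequencies are unambiguous.
Strand depths are drawn once per strand per position; at heteroplasmic
sites the minor count is binomial around the true frequency on each
strand independently, with an optional multiplier on the reverse
strand (`strand_bias`, 0 = single-strand artifact) for testing
double-strand validation. Sequencing errors are spread uniformly over
the three non-consensus bases.

Phenotypes are 0–4 ordinal frequency/severity pairs per symptom, with
distress = frequency × severity (0–16) by construction. Configured
effects shift carriers' latent scores additively before
discretization; a shift targeted at a distress phenotype is split
equally between the two latents so the expected product moves by
approximately the requested amount. Case/control status itself carries
no genetic effect: the generator's null matches the study design where
disease status showed no mtDNA association, and controls are matched
to cases marginally (sex copied, age within ±5 years) rather than by
an explicit pairing variable.

What the generator does **not** emulate: linkage between variants
beyond tree structure, position-dependent error or coverage profiles,
NUMT contamination, indels, population stratification and realistic
haplogroup frequency skew. Passing tests therefore demonstrate the
pipeline's correctness under its stated model — gates, validation
rules, statistics and their calibration — not robustness to artifacts
that the out-of-scope upstream QC is responsible for removing.

## Numerical and design choices

* Randomness flows exclusively through `numpy.random.default_rng`
  seeded from explicit parameters; identical seeds give byte-identical
  pileup files and result tables.
* The r×2 Monte Carlo p uses a log-probability tolerance of
  `1e-9·|log p_obs|` when comparing table probabilities, absorbing
  float rounding in the tie set.
* Logistic fits run at most 100 Newton iterations; non-convergence is
  an error, never a silently accepted estimate.
* Exported pileups encode the consensus-matching base as `.`/`,` and
  substitutions as (upper/lower-case) letters, with constant PHRED-40
  quality characters; depth-0 positions are omitted.
* Problem sizes in the test and acceptance runs (e.g. 10,000 random
  tables for the Fisher oracle, 1,000-replicate null calibrations,
  ~1,500 injected heteroplasmies for sensitivity, a 40-individual
  demo on a 2 kb reference) are chosen so the full validation suite
  completes in a few minutes while keeping every Monte Carlo margin
  comfortably away from its acceptance band.

## Known limitations

* The classification score is a transparent stand-in; equivalence with
  proprietary classifier rankings cannot be asserted, only structural
  correctness on variant-defined trees.
* Heteroplasmies below the 1% rule are out of scope by design, as are
  likelihood-ratio error models, phasing and IUPAC-aware consensus.
* No kinship, population-structure or mixed-model correction is
  applied in the association layer.
* The exact r×2 enumeration is exponential in principle; above the
  configurable total-count bound the Monte Carlo path with a reported
  standard error is the supported route.
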