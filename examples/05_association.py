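"""Haplogroup case-control tests on published counts, plus a symptom scan.

Reproduces the per-haplogroup Fisher statistics of a 193-case /
196-control cohort from its published carrier counts, then runs a
covariate-adjusted haplogroup x symptom scan on a simulated cohort with
a planted effect.
"""

import pandas as pd

from mitocohort import (
    ContingencyTable2x2,
    Effect,
    SimulationParams,
    bh_adjust,
    fisher_2x2,
    haplogroup_symptom_scan,
    simulate_cohort,
    simulate_haplogroup_tree,
    simulate_reference,
)

# carrier counts (cases, controls) per major haplogroup; 193 cases, 196 controls
counts = {
    "A": (2, 4), "B": (2, 2), "C": (0, 3), "D": (0, 1), "F": (0, 1),
    "G": (0, 1), "H": (81, 70), "I": (4, 7), "J": (12, 10), "K": (20, 15),
    "L": (6, 11), "M": (2, 1), "N": (2, 1), "R": (1, 0), "T": (14, 28),
    "U": (28, 31), "V": (6, 3), "W": (2, 2), "X": (4, 2), "HV": (7, 3),
}
results = {
    name: fisher_2x2(ContingencyTable2x2(a, b, 193 - a, 196 - b))
    for name, (a, b) in counts.items()
}
qs = dict(zip(counts, bh_adjust([r.p for r in results.values()])))
print("haplogroup  OR      95% CI           p      q")
for name in ("T", "H", "J", "M"):
    r = results[name]
    print(f"{name:<10s}  {r.odds_ratio:.2f}  {r.ci_low:.2f} - {r.ci_high:<6.2f}"
          f"  {r.p:.2f}  {qs[name]:.2f}")
print("Haplogroup T is nominally enriched in controls (OR 0.47, p 0.03)")
print("but does not survive FDR correction across the 20 haplogroups.")
print()

# planted effect: carriers of clade H score ~3 points higher on bloating distress
reference = simulate_reference(16569, seed=1)
tree = simulate_haplogroup_tree(5, 2, 10, reference, seed=2)
truth = simulate_cohort(
    tree, reference, SimulationParams(n_cases=97, n_controls=96, seed=7),
    effects=(Effect("H", "bloating_distress", 3.0),),
)
pheno = truth.phenotype_frame()
indicators = pd.DataFrame(
    {c: [float(i.haplogroup.startswith(c)) for i in truth.individuals]
     for c in "HUTKJ"},
    index=pheno.index,
)
covariates = pd.DataFrame(
    {"sex": (pheno["sex"] == "F").astype(float), "age": pheno["age"].astype(float)},
    index=pheno.index,
)
scan = haplogroup_symptom_scan(
    indicators, pheno[["bloating_distress", "joint_pain_distress"]], covariates
)
print(scan[["marker", "phenotype", "effect", "p", "q", "significant"]]
      .to_string(index=False))
print()
print("The planted haplogroup-H effect on bloating distress is flagged at")
print("5% FDR (BH within each phenotype across the 5 clades); the")
print("unaffected joint-pain phenotype stays null.")
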