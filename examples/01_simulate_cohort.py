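"""Generate a synthetic mtDNA cohort and inspect its ground truth.

The generator emulates a deep-sequenced case-control cohort: a circular
reference, a shallow haplogroup tree, per-individual variant sets,
low-frequency heteroplasmies and ordinal symptom scores.
"""

import numpy as np

from mitocohort import (
    SimulationParams,
    simulate_cohort,
    simulate_haplogroup_tree,
    simulate_reference,
)

reference = simulate_reference(16569, seed=1)
tree = simulate_haplogroup_tree(
    n_major=5, depth=2, variants_per_branch=10, reference=reference, seed=2
)
params = SimulationParams(n_cases=193, n_controls=196, seed=3)
truth = simulate_cohort(tree, reference, params)

n_variants = [len(i.variants) for i in truth.individuals]
n_hets = [len(i.heteroplasmies) for i in truth.individuals]
clades = {}
for ind in truth.individuals:
    clades[ind.haplogroup[0]] = clades.get(ind.haplogroup[0], 0) + 1

print(f"individuals: {len(truth.individuals)} "
      f"({sum(i.status == 'case' for i in truth.individuals)} cases)")
print(f"variants per individual: {np.mean(n_variants):.1f} "
      f"± {np.std(n_variants):.1f}  (haplogroup-defining + private)")
print(f"heteroplasmies per individual: {np.mean(n_hets):.2f} "
      f"(injected at 1-10% minor frequency)")
print("major-clade counts:", dict(sorted(clades.items())))
print()
print("Variant counts in the low twenties and ~1.3 heteroplasmies per")
print("individual mirror a deep-coverage human mtDNA cohort; every value")
print("above is recorded truth, so downstream callers can be scored exactly.")
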