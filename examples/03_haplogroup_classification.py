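"""Classify variant sets onto a haplogroup tree and build clade indicators.

Each clade is scored by the symmetric mean of recall and precision
between its expected (path-cumulative) variants and the observed set;
the best-scoring clade wins, deeper clades win ties.
"""

from mitocohort import (
    SimulationParams,
    VariantSet,
    classify,
    haplogroup_covariates,
    simulate_cohort,
    simulate_haplogroup_tree,
    simulate_reference,
)

reference = simulate_reference(16569, seed=1)
tree = simulate_haplogroup_tree(5, 2, 10, reference, seed=2)
truth = simulate_cohort(
    tree, reference, SimulationParams(n_cases=60, n_controls=60, seed=5)
)

assignments = [
    classify(VariantSet(i.individual_id, i.variants), tree)
    for i in truth.individuals
]
accuracy = sum(
    a.haplogroup == i.haplogroup for a, i in zip(assignments, truth.individuals)
) / len(assignments)
indicators = haplogroup_covariates(assignments, min_freq=0.05)

print(f"classification accuracy vs truth: {accuracy:.1%}")
print(f"example assignment: {assignments[0].individual_id} -> "
      f"{assignments[0].haplogroup} (score {assignments[0].score:.2f})")
print(f"clades above the 5% cohort-frequency gate: {list(indicators.columns)}")
print(f"indicator table shape: {indicators.shape} (one 0/1 column per clade)")
print()
print("Scores of 1.0 mean the observed variants equal the clade's expected")
print("set exactly; private variants only lower the precision term, so the")
print("true clade still ranks first. The indicator columns feed the")
print("haplogroup association scans as binary covariates.")
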