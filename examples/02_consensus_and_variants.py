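"""Call a consensus sequence from strand-specific counts and recover variants.

The consensus allele is the major allele by combined forward+reverse
count, but only at positions with >= 10x coverage on each strand;
everything else is reported missing.
"""

import numpy as np

from mitocohort import (
    SimulationParams,
    call_consensus,
    extract_variants,
    simulate_cohort,
    simulate_haplogroup_tree,
    simulate_reference,
    simulate_strand_counts,
)

reference = simulate_reference(16569, seed=1)
tree = simulate_haplogroup_tree(5, 2, 10, reference, seed=2)
params = SimulationParams(n_cases=1, n_controls=1, seed=4)
truth = simulate_cohort(tree, reference, params)
ind = truth.individuals[0]

rng = np.random.default_rng(4)
pileup = simulate_strand_counts(ind, reference, params, rng)
profile = call_consensus(pileup, min_strand_depth=10)
variants = extract_variants(profile, reference)

print(f"individual {ind.individual_id} (haplogroup {ind.haplogroup})")
print(f"mean per-strand depth: {pileup.forward_depth().mean():.0f}x")
print(f"positions missing after the 10x-per-strand gate: {profile.missing_count}")
print(f"called variants vs reference: {variants.count} "
      f"(truth: {len(ind.variants)})")
print(f"exact match with truth: {variants.variants == ind.variants}")
print()
print("At ~1500x per strand the coverage gate rarely triggers and the")
print("called variant set reproduces the simulated genome exactly;")
print("sequencing error at 0.1% never reaches consensus scale.")
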