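import numpy as np
import pytest

from mitocohort import (
    SimulationParams,
    StrandPileup,
    simulate_cohort,
    simulate_haplogroup_tree,
    simulate_reference,
)


@pytest.fixture(scope="session")
def reference():
    return simulate_reference(2000, seed=11)


@pytest.fixture(scope="session")
def tree(reference):
    return simulate_haplogroup_tree(
        n_major=5, depth=2, variants_per_branch=3, reference=reference, seed=12
    )


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        n_cases=15,
        n_controls=15,
        depth_mean=300.0,
        depth_dispersion=20.0,
        error_rate=0.001,
        het_rate=2.0,
        het_freq_range=(0.03, 0.10),
        seed=13,
    )


@pytest.fixture(scope="session")
def truth(tree, reference, small_params):
    return simulate_cohort(tree, reference, small_params)


def build_pileup(length, fwd_rows=None, rev_rows=None, individual_id="ind",
                 reference_name="chrM"):
    """StrandPileup with explicit per-position count rows.

    ``fwd_rows``/``rev_rows`` map 1-based positions to (A, C, G, T)
    count tuples; everything else is zero.
    """
    fwd = np.zeros((length, 4), dtype=np.int64)
    rev = np.zeros((length, 4), dtype=np.int64)
    for rows, mat in ((fwd_rows, fwd), (rev_rows, rev)):
        if rows:
            for pos, counts in rows.items():
                mat[pos - 1] = counts
    return StrandPileup(
        individual_id=individual_id, reference_name=reference_name, fwd=fwd, rev=rev
    )
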