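"""Synthetic-cohort generator: structure, determinism and truth fidelity."""

import hashlib
import os

import numpy as np
import pytest
from scipy import stats

from mitocohort import (
    ConfigurationError,
    Effect,
    InvalidParameterError,
    SimulationParams,
    cumulative_variants,
    emit_pileups,
    read_strand_pileups,
    simulate_cohort,
    simulate_haplogroup_tree,
    simulate_reference,
    simulate_strand_counts,
)
from mitocohort.simulate import IndividualTruth


class TestReference:
    def test_length_and_alphabet(self):
        ref = simulate_reference(16569, seed=1)
        assert ref.length == 16569
        assert set(ref.sequence) <= set("ACGT")

    def test_deterministic(self):
        assert simulate_reference(16569, seed=1).sequence == \
            simulate_reference(16569, seed=1).sequence

    def test_uniform_composition(self):
        ref = simulate_reference(2000, seed=7)
        for b in "ACGT":
            assert abs(ref.sequence.count(b) / 2000 - 0.25) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_reference(500, seed=1)


class TestTree:
    def test_structure(self, reference):
        t = simulate_haplogroup_tree(5, 2, 3, reference, seed=2)
        assert len(t.children(t.root)) == 5
        for major in t.children(t.root):
            assert t.depth(major) == 1
            kids = t.children(major)
            assert len(kids) == 1 and t.depth(kids[0]) == 2
        for name, node in t.nodes.items():
            if name != t.root:
                assert len(node.variants) == 3

    def test_root_has_no_defining_variants(self, tree):
        assert tree.nodes[tree.root].variants == frozenset()

    def test_no_position_reused_along_any_path(self, tree):
        for leaf in tree.leaves():
            positions = [
                pos
                for name in tree.path_from_root(leaf)
                for pos, _ in tree.nodes[name].variants
            ]
            assert len(positions) == len(set(positions))

    def test_two_leaves_disjoint(self, reference):
        t = simulate_haplogroup_tree(2, 1, 2, reference, seed=3)
        a, b = t.leaves()
        assert not (cumulative_variants(t, a) & cumulative_variants(t, b))

    def test_impossible_allocation(self, reference):
        with pytest.raises(InvalidParameterError):
            simulate_haplogroup_tree(10, 20, 20, reference, seed=1)


class TestCohort:
    def test_requested_sizes_and_labels(self, tree, reference):
        params = SimulationParams(n_cases=193, n_controls=196, seed=5)
        truth = simulate_cohort(tree, reference, params)
        statuses = [i.status for i in truth.individuals]
        assert len(truth.individuals) == 389
        assert statuses.count("case") == 193
        assert statuses.count("control") == 196

    def test_distress_is_frequency_times_severity(self, truth):
        for ind in truth.individuals:
            for name, value in ind.phenotypes.items():
                if name.endswith("_distress"):
                    stem = name[: -len("_distress")]
                    assert value == (
                        ind.phenotypes[f"{stem}_frequency"]
                        * ind.phenotypes[f"{stem}_severity"]
                    )
                elif name.endswith(("_frequency", "_severity")):
                    assert 0 <= value <= 4

    def test_heteroplasmy_truth_invariants(self, truth, reference):
        for ind in truth.individuals:
            variant_positions = {p for p, _ in ind.variants}
            for pos, minor, freq in ind.heteroplasmies:
                assert 0 < freq <= 0.5
                assert 1 <= pos <= reference.length
                assert pos not in variant_positions

    def test_unknown_effect_rejected(self, tree, reference, small_params):
        with pytest.raises(ConfigurationError):
            simulate_cohort(
                tree, reference, small_params,
                effects=(Effect("NOPE", "joint_pain_severity", 1.0),),
            )
        with pytest.raises(ConfigurationError):
            simulate_cohort(
                tree, reference, small_params,
                effects=(Effect("H", "no_such_phenotype", 1.0),),
            )

    def test_null_effects_produce_no_association(self, tree, reference):
        """Without configured effects, carrier status is independent of phenotype."""
        params = SimulationParams(n_cases=100, n_controls=100, seed=0)
        hits = 0
        for seed in range(100):
            truth = simulate_cohort(tree, reference, params, seed=1000 + seed)
            scores, carrier = [], []
            for ind in truth.individuals:
                scores.append(ind.phenotypes["joint_pain_distress"])
                carrier.append(ind.haplogroup.startswith("H"))
            scores = np.array(scores)
            carrier = np.array(carrier)
            if carrier.any() and (~carrier).any():
                p = stats.ttest_ind(scores[carrier], scores[~carrier]).pvalue
                if p < 0.01:
                    hits += 1
        assert hits <= 5

    def test_effect_shifts_carriers(self, tree, reference):
        params = SimulationParams(n_cases=300, n_controls=300, seed=9)
        eff = Effect("H", "bloating_severity", 1.5)
        truth = simulate_cohort(tree, reference, params, effects=(eff,))
        vals = {"H": [], "other": []}
        for ind in truth.individuals:
            key = "H" if ind.haplogroup.startswith("H") else "other"
            vals[key].append(ind.phenotypes["bloating_severity"])
        assert np.mean(vals["H"]) - np.mean(vals["other"]) > 0.8


class TestPileups:
    def test_noise_free_pileups_are_monoallelic(self, tree, reference, tmp_path):
        params = SimulationParams(
            n_cases=2, n_controls=2, depth_mean=100, error_rate=0.0,
            het_rate=0.0, seed=21,
        )
        truth = simulate_cohort(tree, reference, params)
        manifest = emit_pileups(truth, reference, params, tmp_path)
        by_id = {i.individual_id: i for i in truth.individuals}
        for row in manifest.itertuples():
            sp = read_strand_pileups(
                tmp_path / row.forward, tmp_path / row.reverse, reference
            )
            ind = by_id[row.individual_id]
            alt = dict(ind.variants)
            combined = sp.fwd + sp.rev
            for pos in range(1, reference.length + 1):
                expected = alt.get(pos, reference.base(pos))
                nonzero = np.flatnonzero(combined[pos - 1])
                assert len(nonzero) <= 1
                if len(nonzero) == 1:
                    assert "ACGT"[nonzero[0]] == expected

    def test_manifest_lists_two_files_per_individual(self, truth, reference,
                                                     small_params, tmp_path):
        manifest = emit_pileups(truth, reference, small_params, tmp_path)
        assert len(manifest) == len(truth.individuals)
        files = [f for f in os.listdir(tmp_path) if f.endswith(".pileup")]
        assert len(files) == 2 * len(truth.individuals)

    def test_emit_deterministic(self, tree, reference, tmp_path):
        params = SimulationParams(n_cases=2, n_controls=2, depth_mean=100, seed=31)
        truth = simulate_cohort(tree, reference, params)

        def digest(d):
            h = hashlib.sha256()
            for name in sorted(os.listdir(d)):
                h.update(name.encode())
                h.update((d / name).read_bytes())
            return h.hexdigest()

        emit_pileups(truth, reference, params, tmp_path / "a")
        emit_pileups(truth, reference, params, tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_counts_conserve_depth(self, truth, reference, small_params):
        rng = np.random.default_rng(0)
        sp = simulate_strand_counts(truth.individuals[0], reference, small_params, rng)
        assert (sp.fwd.sum(axis=1) == sp.forward_depth()).all()
        assert (sp.fwd >= 0).all() and (sp.rev >= 0).all()

    def test_heteroplasmy_frequency_recovery(self, reference):
        """At 10% truth and ~1000x depth, observed strand frequencies
        concentrate in [0.07, 0.13] (binomial tail bound)."""
        hets = tuple(
            (pos, "A" if reference.base(pos) != "A" else "C", 0.10)
            for pos in range(1, 101)
        )
        ind = IndividualTruth(
            individual_id="x", status="case", sex="F", age=40, site="Boston",
            haplogroup="H", variants=frozenset(), heteroplasmies=hets,
            phenotypes={},
        )
        params = SimulationParams(
            depth_mean=1000, depth_dispersion=5000, error_rate=0.0, seed=1
        )
        rng = np.random.default_rng(17)
        sp = simulate_strand_counts(ind, reference, params, rng)
        ok = 0
        for pos, minor, _ in hets:
            idx = "ACGT".index(minor)
            f = sp.fwd[pos - 1, idx] / sp.forward_depth()[pos - 1]
            r = sp.rev[pos - 1, idx] / sp.reverse_depth()[pos - 1]
            if 0.07 <= f <= 0.13 and 0.07 <= r <= 0.13:
                ok += 1
        assert ok >= 99
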