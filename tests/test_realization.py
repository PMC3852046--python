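from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

import dlrs
from _oracles import enumerate_realizations, enumerate_reconciliations
from conftest import build_gene_tree, congruent_family, random_tiny_instance
from dlrs.realization import (
    check_realization_sound,
    reconciliation_probability,
    to_reconciliation,
)


def chi2_pvalue(counter, probs, n):
    keys = [a for a, p in probs.items() if p * n >= 5]
    exp = np.array([probs[a] * n for a in keys])
    obs = np.array([counter.get(a, 0) for a in keys], dtype=float)
    if n - exp.sum() > 0:
        exp = np.append(exp, n - exp.sum())
        obs = np.append(obs, n - obs.sum())
    _, p = chisquare(obs, exp * obs.sum() / exp.sum())
    return p


class TestSampling:
    def test_degenerate_support_returns_the_unique_realization(self, species3):
        fam = congruent_family(species3)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        sd = dlrs.discretize(species3, 2)
        table = dlrs.compute_s_table(fam, params, sd)
        sig = fam.sigma_map(species3.topology)
        expected = {u: sd.of_species[sig[u]] for u in fam.gene_tree.vertices()}
        expected[fam.gene_tree.planted_root] = sd.planted_root
        for seed in (0, 1, 2):
            alpha = dlrs.sample_drealization(table, seed)
            assert alpha.as_dict() == expected

    def test_same_seed_same_sample(self, species3):
        fam = build_gene_tree((("A", "B"), ("A", "C")), species3)
        params = dlrs.ModelParams(0.5, 0.4, 1.0, 0.5)
        table = dlrs.compute_s_table(fam, params, dlrs.discretize(species3, 3))
        assert dlrs.sample_drealization(table, 99) == dlrs.sample_drealization(table, 99)

    def test_samples_are_sound(self):
        rng = np.random.default_rng(3)
        fam, params, sd = random_tiny_instance(rng)
        table = dlrs.compute_s_table(fam, params, sd)
        for seed in range(20):
            alpha = dlrs.sample_drealization(table, seed)
            check_realization_sound(alpha.as_dict(), fam, sd)

    def test_sampling_matches_enumerated_probabilities(self, species2):
        fam = build_gene_tree(("A", ("A", "B")), species2)
        params = dlrs.ModelParams(0.6, 0.4, 1.0, 0.5)
        sd = dlrs.discretize(species2, 3)
        table = dlrs.compute_s_table(fam, params, sd)
        total = table.total()
        probs = {a: d / total for a, d in enumerate_realizations(fam, params, sd)}
        rng = np.random.default_rng(11)
        n = 20_000
        cnt = Counter(dlrs.sample_drealization(table, rng) for _ in range(n))
        assert chi2_pvalue(cnt, probs, n) > 0.001


class TestMAP:
    def test_single_realization_instance_max_equals_sum(self, species3):
        fam = congruent_family(species3)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        sd = dlrs.discretize(species3, 2)
        s = dlrs.compute_s_table(fam, params, sd)
        m = dlrs.compute_m_table(fam, params, sd)
        assert m.total() == pytest.approx(s.total(), rel=1e-12)

    def test_map_equals_enumeration_argmax(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            fam, params, sd = random_tiny_instance(rng)
            m = dlrs.compute_m_table(fam, params, sd)
            alpha, prob = dlrs.map_drealization(m)
            enum = enumerate_realizations(fam, params, sd)
            best_alpha, best_d = max(enum, key=lambda t: t[1])
            assert prob == pytest.approx(best_d, rel=1e-12)
            assert alpha == best_alpha

    def test_map_probability_bounded_by_total(self):
        rng = np.random.default_rng(13)
        fam, params, sd = random_tiny_instance(rng)
        assert dlrs.compute_m_table(fam, params, sd).total() <= \
            dlrs.compute_s_table(fam, params, sd).total() * (1 + 1e-12)


class TestProjection:
    def test_projection_quotients_interior_points(self, species2):
        fam = build_gene_tree(("A", ("A", "B")), species2)
        params = dlrs.ModelParams(0.6, 0.4, 1.0, 0.5)
        sd = dlrs.discretize(species2, 3)
        enum = enumerate_realizations(fam, params, sd)
        gammas = {}
        for alpha, _ in enum:
            gamma = to_reconciliation(alpha, sd)
            for u, v in alpha.mapping:
                kind, ident = gamma.as_dict()[u]
                if sd.is_species(v):
                    assert kind == "vertex" and sd.of_species[ident] == v
                else:
                    assert kind == "edge" and v in sd.edge_points[ident]
            gammas.setdefault(gamma, []).append(alpha)
        # at least one reconciliation groups several realizations
        assert any(len(v) > 1 for v in gammas.values())


class TestReconciliationProbability:
    def test_sums_to_generation_probability(self):
        rng = np.random.default_rng(21)
        for _ in range(4):
            fam, params, sd = random_tiny_instance(rng)
            total = dlrs.generation_probability(fam, params, sd)
            acc = sum(
                reconciliation_probability(fam, params, sd, g)
                for g in enumerate_reconciliations(fam, params, sd)
            )
            assert acc == pytest.approx(total, rel=1e-10)

    def test_unique_realization_projection_has_full_mass(self, species3):
        fam = congruent_family(species3)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        sd = dlrs.discretize(species3, 2)
        table = dlrs.compute_s_table(fam, params, sd)
        gamma = to_reconciliation(dlrs.sample_drealization(table, 0), sd)
        assert reconciliation_probability(fam, params, sd, gamma) == \
            pytest.approx(table.total(), rel=1e-12)

    def test_unsound_gamma_raises(self, species3):
        fam = build_gene_tree((("A", "B"), "C"), species3)
        params = dlrs.ModelParams(0.3, 0.2, 1.0, 0.5)
        sd = dlrs.discretize(species3, 2)
        m = dlrs.mpr(fam, species3.topology)
        gamma = m.reconciliation.as_dict()
        G = fam.gene_tree
        root_child = [u for u in G.children[G.root] if not G.is_leaf(u)][0]
        # put a child strictly above its parent
        gamma[root_child] = ("vertex", species3.topology.planted_root)
        with pytest.raises(ValueError):
            reconciliation_probability(fam, params, sd, gamma)

    def test_zero_support_gamma(self, species2):
        """A sound gamma whose R-set excludes all DP support has density 0."""
        fam = congruent_family(species2)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        sd = dlrs.discretize(species2, 2)
        G, top = fam.gene_tree, species2.topology
        gamma = dlrs.mpr(fam, top).reconciliation.as_dict()
        gamma[G.root] = ("edge", top.root)  # duplication needs lambda > 0
        assert reconciliation_probability(fam, params, sd, gamma) == 0.0

    def test_three_code_paths_agree_on_sampled_frequencies(self, species2):
        """Sampling, gamma-restricted DP and total DP are mutually consistent."""
        fam = build_gene_tree(("B", ("A", "B")), species2)
        params = dlrs.ModelParams(0.7, 0.5, 1.0, 0.4)
        sd = dlrs.discretize(species2, 2)
        table = dlrs.compute_s_table(fam, params, sd)
        total = table.total()
        probs = {
            g: reconciliation_probability(fam, params, sd, g) / total
            for g in enumerate_reconciliations(fam, params, sd)
        }
        rng = np.random.default_rng(17)
        n = 20_000
        cnt = Counter(
            to_reconciliation(dlrs.sample_drealization(table, rng), sd)
            for _ in range(n)
        )
        assert chi2_pvalue(cnt, probs, n) > 0.001
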