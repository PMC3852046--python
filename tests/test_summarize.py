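import numpy as np
import pytest
from scipy.stats import spearmanr

import dlrs
from conftest import build_gene_tree, congruent_family
from dlrs.realization import DRealization
from dlrs.summarize import (
    FamilySamples,
    accumulate_duplications,
    heatmap_newick,
    heatmap_table,
    mpr_summary,
    normalize_heatmap,
)


def sample_block(species, fam, params, sd, n, seed):
    table = dlrs.compute_s_table(fam, params, sd)
    rng = np.random.default_rng(seed)
    return [dlrs.sample_drealization(table, rng) for _ in range(n)]


class TestAccumulate:
    def test_no_duplications_anywhere(self, species3):
        sd = dlrs.discretize(species3, 2)
        fam = congruent_family(species3)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        counts = accumulate_duplications(
            [sample_block(species3, fam, params, sd, 5, 0)], sd
        )
        assert all(v == 0.0 for v in counts.values())

    def test_single_duplication_is_an_indicator(self, species2):
        sd = dlrs.discretize(species2, 2)
        fam = build_gene_tree((("A", "B"), ("A", "B")), species2)
        params = dlrs.ModelParams(0.3, 0.2, 1.0, 0.5)
        table = dlrs.compute_s_table(fam, params, sd)
        alpha = dlrs.sample_drealization(table, 3)
        counts = accumulate_duplications([[alpha]], sd)
        dup_vertices = [
            v for _, v in alpha.mapping if not sd.is_species(v)
        ]
        assert sum(counts.values()) == pytest.approx(len(dup_vertices))
        for v in dup_vertices:
            assert counts[v] == 1.0

    def test_mass_conservation(self, species2):
        """Sum of counts = mean duplication count per family, summed."""
        sd = dlrs.discretize(species2, 3)
        params = dlrs.ModelParams(0.6, 0.3, 1.0, 0.5)
        fams = [
            build_gene_tree((("A", "B"), ("A", "B")), species2),
            build_gene_tree(("A", ("A", "B")), species2),
        ]
        blocks = [sample_block(species2, f, params, sd, 40, i) for i, f in enumerate(fams)]
        counts = accumulate_duplications(blocks, sd)
        expected = sum(
            np.mean([
                sum(1 for _, v in a.mapping if not sd.is_species(v))
                for a in block
            ])
            for block in blocks
        )
        assert sum(counts.values()) == pytest.approx(expected)


class TestNormalize:
    def test_endpoints_hit_zero_and_ten(self, species2):
        sd = dlrs.discretize(species2, 3)
        interior = [v for v in range(sd.n_vertices) if not sd.is_species(v)]
        counts = {v: 0.0 for v in range(sd.n_vertices)}
        for i, v in enumerate(interior):
            counts[v] = float(i)
        levels = normalize_heatmap(counts, sd, mode="global")
        vals = [levels[v] for v in interior]
        assert min(vals) == 0 and max(vals) == 10

    def test_monotone_in_counts(self, species2):
        sd = dlrs.discretize(species2, 4)
        interior = [v for v in range(sd.n_vertices) if not sd.is_species(v)]
        rng = np.random.default_rng(0)
        counts = {v: float(rng.uniform(0, 7)) for v in interior}
        levels = normalize_heatmap(counts, sd, mode="global")
        for a in interior:
            for b in interior:
                if counts[a] <= counts[b]:
                    assert levels[a] <= levels[b]

    def test_uniform_counts_per_edge_degenerate_rule(self, species2):
        sd = dlrs.discretize(species2, 3)
        counts = {v: 2.5 for v in range(sd.n_vertices) if not sd.is_species(v)}
        levels = normalize_heatmap(counts, sd, mode="per-edge")
        assert all(lv == 10 for lv in levels.values())
        zero = {v: 0.0 for v in counts}
        assert all(lv == 0 for lv in normalize_heatmap(zero, sd, mode="per-edge").values())

    def test_excluding_edge_equals_deleting_it(self, species3):
        sd = dlrs.discretize(species3, 2)
        rng = np.random.default_rng(1)
        counts = {
            v: float(rng.uniform(0, 5))
            for v in range(sd.n_vertices) if not sd.is_species(v)
        }
        top_edge = sd.base.topology.root  # the planted ("common ancestral") edge
        excl = normalize_heatmap(
            counts, sd, mode="global-excluding", excluded_edges={top_edge}
        )
        reduced = {
            v: c for v, c in counts.items()
            if v not in sd.edge_points[top_edge]
        }
        direct = normalize_heatmap(reduced, sd, mode="global-excluding",
                                   excluded_edges={top_edge})
        assert excl == direct
        assert not any(v in excl for v in sd.edge_points[top_edge])

    def test_all_zero_domain(self, species2):
        sd = dlrs.discretize(species2, 2)
        counts = {v: 0.0 for v in range(sd.n_vertices)}
        levels = normalize_heatmap(counts, sd, mode="global")
        assert set(levels.values()) == {0}

    def test_table_and_newick_render(self, species3):
        sd = dlrs.discretize(species3, 2)
        counts = {v: 1.0 for v in range(sd.n_vertices) if not sd.is_species(v)}
        levels = normalize_heatmap(counts, sd, mode="global")
        df = heatmap_table(counts, levels, sd)
        assert set(df.columns) == {"edge", "point", "age", "count", "level"}
        assert len(df) == len(levels)
        nwk = heatmap_newick(levels, sd)
        assert "&levels=" in nwk


class TestMPRSummary:
    def test_no_duplication_cohort_is_identical_to_mpr(self, species3):
        sd = dlrs.discretize(species3, 2)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        fam = congruent_family(species3)
        alphas = sample_block(species3, fam, params, sd, 10, 0)
        cohort = [FamilySamples("f0", [
            (fam, dlrs.to_reconciliation(a, sd)) for a in alphas
        ])]
        df = mpr_summary(cohort, species3.topology)
        assert df.attrs["fraction_differing"] == 0.0
        assert df.loc[0, "fraction_identical_mpr"] == 1.0
        assert df.loc[0, "expected_avg_distance"] == 0.0
        assert df.loc[0, "expected_max_distance"] == 0.0

    def test_constant_distance_family(self, species3):
        """All samples at avg distance 0.5 -> expected avg 0.5 exactly."""
        fam = build_gene_tree((("A", "B"), ("A", "C")), species3)
        S, G = species3.topology, fam.gene_tree
        m = dlrs.mpr(fam, S).reconciliation
        d = m.as_dict()
        u = next(u for u, (k, _) in m.mapping
                 if k == "vertex" and not G.is_leaf(u) and u != G.planted_root)
        moved = dict(d)
        moved[u] = ("edge", d[u][1])
        g2 = dlrs.Reconciliation.from_dict(moved)
        per_sample = dlrs.compare.distance_avg(S, G, g2, m)
        cohort = [FamilySamples("f0", [(fam, g2)] * 7)]
        df = mpr_summary(cohort, S)
        assert df.loc[0, "expected_avg_distance"] == pytest.approx(per_sample)
        assert df.loc[0, "fraction_identical_mpr"] == 0.0

    def test_cohort_fraction_is_weighted_mean_identity(self, species2):
        sd = dlrs.discretize(species2, 2)
        params = dlrs.ModelParams(0.5, 0.3, 1.0, 0.5)
        fams = [
            build_gene_tree((("A", "B"), ("A", "B")), species2),
            build_gene_tree(("A", ("A", "B")), species2),
        ]
        cohort = []
        ns = [15, 25]
        for i, (f, n) in enumerate(zip(fams, ns)):
            alphas = sample_block(species2, f, params, sd, n, 10 + i)
            cohort.append(FamilySamples(
                f"f{i}", [(f, dlrs.to_reconciliation(a, sd)) for a in alphas]
            ))
        df = mpr_summary(cohort, species2.topology)
        weighted = sum(
            df.loc[i, "fraction_identical_mpr"] * ns[i] for i in range(2)
        ) / sum(ns)
        assert df.attrs["fraction_differing"] == pytest.approx(1.0 - weighted)


class TestMAPReconciliationEstimates:
    def test_both_estimators_agree_on_degenerate_support(self, species3):
        from dlrs.summarize import map_reconciliation_estimates

        fam = congruent_family(species3)
        params = dlrs.ModelParams(0.0, 0.0, 1.0, 0.5)
        sd = dlrs.discretize(species3, 2)
        est = map_reconciliation_estimates(fam, params, sd, n_samples=50, seed=1)
        assert est["most_frequent"] == est["map_projection"]
        assert est["most_frequent_support"] == 1.0
        assert est["most_frequent"] == dlrs.mpr(fam, species3.topology).reconciliation

    def test_estimators_labeled_and_supported(self, species2):
        from dlrs.summarize import map_reconciliation_estimates

        fam = build_gene_tree(("A", ("A", "B")), species2)
        params = dlrs.ModelParams(0.6, 0.4, 1.0, 0.5)
        sd = dlrs.discretize(species2, 3)
        est = map_reconciliation_estimates(fam, params, sd, n_samples=400, seed=2)
        assert 0.0 < est["most_frequent_support"] <= 1.0
        # the modal reconciliation maximizes the summed realization posterior
        total = dlrs.generation_probability(fam, params, sd)
        from dlrs.realization import reconciliation_probability
        from _oracles import enumerate_reconciliations

        probs = {g: d / total for g, d in
                 enumerate_reconciliations(fam, params, sd).items()}
        assert est["most_frequent"] == max(probs, key=probs.get)


class TestRecovery:
    def test_inferred_counts_track_true_counts(self, species4):
        """Spearman correlation between inferred and true duplication maps."""
        params = dlrs.ModelParams(0.8, 0.2, 1.0, 0.25)
        sd = dlrs.discretize(species4, 3)
        rng = np.random.default_rng(99)
        blocks, true_counts = [], {v: 0.0 for v in range(sd.n_vertices)}
        n_events = 0
        produced = 0
        while produced < 40:
            sim = dlrs.simulate_family(species4, params, seed=rng, with_sequences=False)
            if sim.degenerate:
                continue
            try:
                true_alpha = sim.true_drealization(sd)
            except ValueError:
                continue
            produced += 1
            for u, v in true_alpha.items():
                if not sd.is_species(v):
                    true_counts[v] += 1.0
                    n_events += 1
            table = dlrs.compute_s_table(sim.family, params, sd)
            blocks.append([dlrs.sample_drealization(table, rng) for _ in range(30)])
        assert n_events >= 50
        inferred = accumulate_duplications(blocks, sd)
        interior = [v for v in range(sd.n_vertices) if not sd.is_species(v)]
        rho, _ = spearmanr(
            [true_counts[v] for v in interior],
            [inferred[v] for v in interior],
        )
        assert rho > 0.0
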