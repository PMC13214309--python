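import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hubdrug.simulate import (
    GroundTruth,
    SimulationConfig,
    simulate_drug_table,
    simulate_expression,
    simulate_gene_sets,
    simulate_interactions,
)


class TestExpression:
    def test_identical_seed_reproduces_outputs_exactly(self, small_config):
        m1, a1, t1 = simulate_expression(small_config)
        m2, a2, t2 = simulate_expression(small_config)
        for x, y in zip(m1, m2):
            pd.testing.assert_frame_equal(x.values, y.values)
        pd.testing.assert_frame_equal(a1, a2)
        assert t1.de_genes == t2.de_genes and t1.hub_genes == t2.hub_genes
        assert t1.true_drug == t2.true_drug

    def test_noiseless_single_gene_logfc_exact(self):
        cfg = SimulationConfig(
            n_genes=50, n_platforms=2, panel_overlap=1.0, n_primary=4, n_metastatic=4,
            n_de=1, effect_size=2.0, noise_sd=0.0, batch_sd=0.0,
            hub_community_size=0, planted_drug_targets=0, n_drugs=0, seed=1,
        )
        matrices, annotation, truth = simulate_expression(cfg)
        ((gene, lfc),) = truth.de_genes.items()
        for m in matrices:
            met = [s for s in m.sample_ids if "M" in s.split("_")[1]]
            pri = [s for s in m.sample_ids if "P" in s.split("_")[1]]
            observed = m.values.loc[gene, met].mean() - m.values.loc[gene, pri].mean()
            assert observed == pytest.approx(lfc, abs=1e-12)

    def test_null_config_t_statistics_are_null(self):
        cfg = SimulationConfig(
            n_genes=400, n_platforms=1, n_de=0, effect_size=0.0,
            hub_community_size=0, planted_drug_targets=0, n_primary=10,
            n_metastatic=10, seed=2,
        )
        matrices, annotation, _ = simulate_expression(cfg)
        met = annotation[annotation.group == "metastatic"]["sample"]
        pri = annotation[annotation.group == "primary"]["sample"]
        t = stats.ttest_ind(matrices[0].values[list(met)], matrices[0].values[list(pri)], axis=1)
        assert stats.kstest(t.pvalue, "uniform").pvalue > 0.01

    def test_batch_offsets_shared_by_groups(self):
        cfg = SimulationConfig(
            n_genes=100, n_platforms=2, panel_overlap=1.0, n_primary=6, n_metastatic=6,
            n_de=0, noise_sd=0.0, batch_sd=3.0, hub_community_size=0,
            planted_drug_targets=0, seed=3,
        )
        matrices, annotation, _ = simulate_expression(cfg)
        for m in matrices:
            pri = [s for s in m.sample_ids if "_P" in s]
            met = [s for s in m.sample_ids if "_M" in s]
            # with no DE and no noise the two group means coincide per platform
            np.testing.assert_allclose(
                m.values[pri].mean(axis=1), m.values[met].mean(axis=1), atol=1e-12
            )
        # but the platforms disagree on the same gene (the batch offset)
        diff = (matrices[0].values.iloc[:, 0] - matrices[1].values.iloc[:, 0]).abs()
        assert diff.mean() > 1.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(SimulationConfig(n_primary=0))
        with pytest.raises(ValueError):
            simulate_expression(SimulationConfig(n_de=5000))
        with pytest.raises(ValueError):
            simulate_expression(SimulationConfig(panel_overlap=1.5))

    def test_panel_overlap_structure(self, small_config):
        matrices, _, _ = simulate_expression(small_config)
        panels = [set(m.gene_ids) for m in matrices]
        shared = set.intersection(*panels)
        assert len(shared) >= round(small_config.panel_overlap * small_config.n_genes)
        union = set.union(*panels)
        assert len(union) == small_config.n_genes

    def test_truth_invariant_targets_are_up_hubs(self, small_config):
        _, _, truth = simulate_expression(small_config)
        up = {g for g, l in truth.de_genes.items() if l > 0}
        assert truth.true_drug_targets <= truth.hub_genes & up


class TestInteractions:
    def test_full_density_community_is_clique(self):
        cfg = SimulationConfig(
            n_genes=100, n_de=10, hub_community_size=5, hub_community_p=1.0,
            planted_drug_targets=1, seed=4,
        )
        _, _, truth = simulate_expression(cfg)
        table = simulate_interactions(cfg, truth)
        hub = sorted(truth.hub_genes)
        pairs = {(a, b) for a, b, _ in table.itertuples(index=False)}
        for i in range(len(hub)):
            for j in range(i + 1, len(hub)):
                assert (hub[i], hub[j]) in pairs
        hub_rows = table[table.gene_a.isin(hub) & table.gene_b.isin(hub)]
        assert (hub_rows["score"] >= 0.8).all()

    def test_deterministic_and_simple(self, small_config):
        _, _, truth = simulate_expression(small_config)
        t1 = simulate_interactions(small_config, truth)
        t2 = simulate_interactions(small_config, truth)
        pd.testing.assert_frame_equal(t1, t2)
        assert not (t1.gene_a == t1.gene_b).any()
        assert not t1.duplicated(["gene_a", "gene_b"]).any()
        assert t1["score"].between(0.4, 1.0).all()

    def test_background_degree_heavy_tailed(self):
        for seed in range(10):
            cfg = SimulationConfig(
                n_genes=2000, n_de=0, hub_community_size=2, planted_drug_targets=0,
                seed=seed,
            )
            table = simulate_interactions(cfg, GroundTruth())
            deg = pd.concat([table.gene_a, table.gene_b]).value_counts()
            full = deg.reindex([f"G{i:06d}" for i in range(1, 2001)], fill_value=0)
            assert full.max() >= 10 * max(full.median(), 1)

    def test_tiny_community_rejected(self, small_config):
        _, _, truth = simulate_expression(small_config)
        bad = SimulationConfig(**{**small_config.__dict__, "hub_community_size": 1,
                                  "planted_drug_targets": 0})
        with pytest.raises(ValueError):
            simulate_interactions(bad, truth)


class TestGeneSetsAndDrugs:
    def test_planted_set_membership(self, small_config):
        _, _, truth = simulate_expression(small_config)
        collection = simulate_gene_sets(small_config, truth)
        planted = collection[0]
        de_frac = len(planted.genes & set(truth.de_genes)) / len(planted.genes)
        assert de_frac >= 0.5
        assert all(len(s.genes) >= 3 for s in collection)

    def test_zero_background_sets(self, small_config):
        _, _, truth = simulate_expression(small_config)
        collection = simulate_gene_sets(small_config, truth, n_background=0)
        assert len(collection) == 1 and collection[0].term_id == "T00000"

    def test_planted_drug_rows_and_decoy_inhibitor_of_down_gene(self, small_config):
        _, _, truth = simulate_expression(small_config)
        table = simulate_drug_table(small_config, truth)
        planted = table[table.drug == truth.true_drug]
        assert len(planted) == small_config.planted_drug_targets
        assert (planted.action == "inhibitor").all()
        assert set(planted.gene) == truth.true_drug_targets
        down = {g for g, l in truth.de_genes.items() if l < 0}
        decoy_rows = table[(table.drug != truth.true_drug) & (table.action == "inhibitor")]
        assert any(g in down for g in decoy_rows.gene)

    def test_single_drug_table_contains_only_planted(self):
        cfg = SimulationConfig(n_genes=200, n_de=20, hub_community_size=6,
                               planted_drug_targets=2, n_drugs=1, seed=5)
        _, _, truth = simulate_expression(cfg)
        table = simulate_drug_table(cfg, truth)
        assert set(table.drug) == {truth.true_drug}

    def test_excess_drug_targets_rejected(self):
        cfg = SimulationConfig(n_genes=200, n_de=2, hub_community_size=6,
                               planted_drug_targets=5, seed=6)
        with pytest.raises(ValueError, match="up-regulated"):
            simulate_expression(cfg)
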