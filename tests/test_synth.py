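import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spcnet
from spcnet.conditions import GROUPING_ORDER, grouping_sizes, samples_for_grouping
from spcnet.synth import (
    SimulationConfig,
    default_config,
    generate_interaction_table,
    generate_ortholog_map,
    generate_spc_dataset,
)


class TestDatasetGeneration:
    def test_design_matches_grouping_sizes(self, default_dataset):
        counts, meta, _ = default_dataset
        assert counts.shape == (300, 27)
        assert grouping_sizes(meta) == {
            "Fe_sufficiency": 12, "Mo_sufficiency": 14,
            "Fe_starvation": 15, "Mo_starvation": 13,
        }

    def test_counts_are_nonnegative_integers(self, default_dataset):
        counts, _, _ = default_dataset
        arr = counts.to_numpy()
        assert arr.dtype.kind == "i" and (arr >= 0).all()

    def test_same_seed_bit_identical(self):
        cfg = default_config(seed=5)
        a = generate_spc_dataset(cfg)
        b = generate_spc_dataset(cfg)
        assert a[0].equals(b[0]) and a[1].equals(b[1]) and a[2] == b[2]

    def test_different_seed_differs(self):
        a = generate_spc_dataset(default_config(seed=1))[0]
        b = generate_spc_dataset(default_config(seed=2))[0]
        assert not a.equals(b)

    def test_ground_truth_consistency(self, default_dataset):
        counts, _, truth = default_dataset
        proteins = set(counts.index)
        for g, hubs in truth.planted_hubs.items():
            assert hubs <= proteins
            assert truth.anchors[g] <= hubs
        assert truth.de_proteins <= proteins
        assert truth.de_proteins.isdisjoint(truth.module_assignment)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError):
            generate_spc_dataset(
                default_config(reps_per_condition={"+Mo+Fe": 27})
            )

    def test_oversized_modules_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_proteins=10, n_modules=4, module_size=10).validate()

    def test_hub_spec_controls_module_grouping(self):
        spec = (
            ("P0001", "Mo_starvation"), ("P0011", "Fe_starvation"),
            ("P0021", "Mo_sufficiency"), ("P0031", "Fe_sufficiency"),
        )
        _, _, truth = generate_spc_dataset(default_config(hub_spec=spec, seed=0))
        assert truth.anchors["Mo_starvation"] == {"P0001"}
        assert truth.module_grouping[0] == "Mo_starvation"

    def test_null_config_edge_rate(self):
        """With no planted structure, the co-expression edge rate at n=13
        stays within the analytical null tail (binomial bound at 0.01)."""
        cfg = default_config(
            seed=17, n_proteins=120, n_modules=0, n_de_proteins=0,
            dropout_midpoint=-30.0, baseline_log_mean_range=(5.0, 7.0),
            background_high_frac=0.0,
        )
        counts, meta, _ = generate_spc_dataset(cfg)
        corr = spcnet.spearman_all_pairs(
            counts, samples_for_grouping(meta, "Mo_starvation")
        )
        iu = np.triu_indices(len(counts), 1)
        hits = int(
            ((np.abs(corr.rho.to_numpy()[iu]) > 0.7)
             & (corr.p_value.to_numpy()[iu] < 0.01)).sum()
        )
        assert hits <= stats.binom.ppf(0.999, len(iu[0]), 0.01)

    def test_planted_hub_attains_max_degree_in_active_grouping(self):
        """The Mo-starvation anchor's degree peaks in the Mo-starvation
        network in >=80% of replicate simulations."""
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            counts, meta, truth = generate_spc_dataset(default_config(seed=1000 + seed))
            nets = spcnet.build_grouping_networks(counts, meta)
            anchor = next(iter(truth.anchors["Mo_starvation"]))
            degs = {
                g: nets[g].degree(anchor) if anchor in nets[g] else 0
                for g in GROUPING_ORDER
            }
            focal = degs["Mo_starvation"]
            wins += focal > 0 and focal == max(degs.values())
        assert wins >= 0.8 * n_rep


class TestOrthologMap:
    def test_mean_homology_near_target(self):
        omap = generate_ortholog_map([f"p{i}" for i in range(500)], 67.0, seed=3)
        assert omap["homology_pct"].mean() == pytest.approx(67.0, abs=3.0)
        assert ((omap["homology_pct"] > 0) & (omap["homology_pct"] <= 100)).all()

    def test_bijection_without_sharing(self):
        omap = generate_ortholog_map(
            [f"p{i}" for i in range(50)], fraction_many_to_one=0.0, seed=0
        )
        assert omap["gene"].nunique() == 50

    def test_many_to_one_fraction(self):
        omap = generate_ortholog_map(
            [f"p{i}" for i in range(100)], fraction_many_to_one=0.2, seed=0
        )
        shared = (omap.groupby("gene")["protein"].count() == 2).sum()
        assert shared == 10  # 20% of 100 proteins in pairs

    def test_deterministic(self):
        proteins = [f"p{i}" for i in range(40)]
        assert generate_ortholog_map(proteins, seed=8).equals(
            generate_ortholog_map(proteins, seed=8)
        )

    def test_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            generate_ortholog_map(["p1"], mean_homology=0.0)


class TestInteractionTable:
    def test_pure_within_module_pairs(self, default_dataset):
        _, _, truth = default_dataset
        table = generate_interaction_table(truth, p_in=1.0, p_out=0.0, seed=0)
        pairs = {tuple(sorted(t)) for t in zip(table["gene_a"], table["gene_b"])}
        assert pairs == set(truth.true_interactions)

    def test_all_subthreshold_scores_filter_to_empty(self, default_dataset):
        _, _, truth = default_dataset
        table = generate_interaction_table(
            truth, p_in=1.0, p_out=0.0, seed=0, frac_subthreshold=1.0
        )
        assert len(spcnet.filter_interactions(table)) == 0

    def test_p_in_below_p_out_rejected(self, default_dataset):
        _, _, truth = default_dataset
        with pytest.raises(ValueError):
            generate_interaction_table(truth, p_in=0.1, p_out=0.5)

    def test_equal_rates_independent_of_modules(self):
        """With p_in == p_out, interaction presence is independent of module
        co-membership (chi-square non-significant at alpha=0.01 in >=18 of
        20 seeds)."""
        _, _, truth = generate_spc_dataset(
            default_config(seed=0, n_proteins=60, module_size=10)
        )
        ok = 0
        within = set(truth.true_interactions)
        module_proteins = sorted(truth.module_assignment)
        all_pairs = [
            (a, b)
            for i, a in enumerate(module_proteins)
            for b in module_proteins[i + 1:]
        ]
        for seed in range(20):
            table = generate_interaction_table(truth, p_in=0.3, p_out=0.3, seed=seed)
            sampled = {tuple(sorted(t)) for t in zip(table["gene_a"], table["gene_b"])}
            contingency = np.zeros((2, 2))
            for pair in all_pairs:
                contingency[pair in within, pair in sampled] += 1
            _, p, _, _ = stats.chi2_contingency(contingency)
            ok += p > 0.01
        assert ok >= 18

    def test_deterministic(self, default_dataset):
        _, _, truth = default_dataset
        a = generate_interaction_table(truth, seed=4)
        assert a.equals(generate_interaction_table(truth, seed=4))
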