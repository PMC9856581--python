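"""Rank-product prioritization and random-walk-with-restart propagation."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import immunoaging as ia


def path_network(*edges) -> ia.PPINetwork:
    return ia.PPINetwork.from_graph(nx.Graph(list(edges)))


class TestPPINetwork:
    def test_column_stochastic_transition_matrix(self, small_network):
        col_sums = np.asarray(small_network.w.sum(axis=0)).ravel()
        assert np.allclose(col_sums, 1.0, atol=1e-12)

    def test_restricts_to_largest_component(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("X", "Y")])
        net = ia.PPINetwork.from_graph(g)
        assert set(net.nodes) == {"A", "B", "C"}
        assert set(net.excluded) == {"X", "Y"}
        with pytest.raises(KeyError):
            net.index_of(["X"])

    def test_drops_self_loops_and_duplicate_edges(self):
        g = nx.MultiGraph([("A", "B"), ("A", "B"), ("A", "A"), ("B", "C")])
        net = ia.PPINetwork.from_graph(g)
        assert net.graph.number_of_edges() == 2


class TestGeneFoldChanges:
    def test_no_difference_means_unit_fold_change(self):
        expr = pd.DataFrame(
            {"t1": [3.0, 8.0], "t2": [3.0, 2.0], "t3": [3.0, 5.0],
             "n1": [3.0, 8.0], "n2": [3.0, 2.0]},
            index=["g_same", "g_also"])
        fc = ia.gene_fold_changes(expr, [True, True, True, False, False],
                                  ages=[40.0, 50.0, 60.0],
                                  tumor_adj_p=1.1, age_raw_p=1.1)
        assert fc["fc1"].loc["g_same"] == pytest.approx(1.0)

    def test_planted_fold_change_interval(self):
        cfg = ia.SimulationConfig(
            n_genes=100, n_cancers=1, n_tumor=200, n_normal=200,
            planted_tumor_lfc=2.0, noise_sd=0.1, cancer_shift_sd=0.0,
            n_driver_genes=5, n_tumor_dysregulated=20, n_age_dysregulated=20,
            network_nodes=100, network_attach=2, n_pathways=2, pathway_size=20,
            seed=5)
        cohort = ia.generate_cohort(cfg)
        meta = cohort.metadata
        fc = ia.gene_fold_changes(cohort.expression, meta["is_tumor"].to_numpy(),
                                  meta.loc[meta["is_tumor"], "age_years"].to_numpy(),
                                  tumor_adj_p=1.1, age_raw_p=1.1)
        up = [g for g in cohort.truth["tumor_dysregulated"]
              if cohort.tumor_signs[g] > 0]
        assert ((fc["fc1"].loc[up] > 3.5) & (fc["fc1"].loc[up] < 4.6)).all()

    def test_degenerate_ages_error(self):
        expr = pd.DataFrame(np.arange(8.0).reshape(2, 4),
                            index=["a", "b"], columns=list("wxyz"))
        with pytest.raises(ValueError):
            ia.gene_fold_changes(expr, [True, True, False, False], ages=[50.0, 50.0],
                                 tumor_adj_p=1.1, age_raw_p=1.1)


class TestRankProduct:
    def test_five_gene_toy(self):
        fc1 = pd.Series(2.0 ** np.array([5.0, 4, 3, 2, 1]), index=list("abcde"))
        fc2 = pd.Series(2.0 ** np.array([1.0, 2, 3, 4, 5]), index=list("abcde"))
        out = ia.rank_product(fc1, fc2)
        assert dict(zip(out["gene"], out["r_img"])) == {
            "a": 5.0, "b": 8.0, "c": 9.0, "d": 8.0, "e": 5.0}
        assert list(out["gene"]) == ["a", "e", "b", "d", "c"]  # ties by symbol

    def test_double_winner_is_first(self):
        fc1 = pd.Series([8.0, 2.0, 1.0], index=["g1", "g2", "g3"])
        fc2 = pd.Series([16.0, 2.0, 1.5], index=["g1", "g2", "g3"])
        out = ia.rank_product(fc1, fc2)
        assert out["gene"].iloc[0] == "g1" and out["r_img"].iloc[0] == 1.0

    def test_input_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(20)]
        fc1 = pd.Series(rng.lognormal(size=20), index=genes)
        fc2 = pd.Series(rng.lognormal(size=20), index=genes)
        perm = rng.permutation(genes)
        a = ia.rank_product(fc1, fc2)
        b = ia.rank_product(fc1.loc[perm], fc2.loc[perm])
        assert list(a["gene"]) == list(b["gene"])

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="different genes"):
            ia.rank_product(pd.Series({"a": 1.0, "b": 2.0}),
                            pd.Series({"a": 1.0, "c": 2.0}))


class TestSeedSelection:
    def _priorities(self, n):
        return pd.DataFrame({"gene": [f"G{i:04d}" for i in range(n)],
                             "r_img": np.arange(1.0, n + 1)})

    def test_ceil_rounding(self, small_network):
        assert len(ia.select_seed_genes(self._priorities(100), small_network, 0.10)) == 10
        assert len(ia.select_seed_genes(self._priorities(101), small_network, 0.10)) == 11

    def test_absent_seeds_dropped_with_log(self, small_network, caplog):
        pri = self._priorities(20)
        pri.loc[0, "gene"] = "NOT_IN_NETWORK"
        with caplog.at_level("WARNING"):
            seeds = ia.select_seed_genes(pri, small_network, 0.10)
        assert "NOT_IN_NETWORK" not in seeds and len(seeds) == 1
        pri_all_bad = pri.iloc[:1]
        with pytest.raises(ValueError):
            ia.select_seed_genes(pri_all_bad, small_network, 1.0)


class TestRwr:
    def test_restart_only_limit(self, small_network):
        seeds = list(small_network.nodes[:4])
        state = ia.rwr(small_network, seeds, gamma=1.0)
        assert np.allclose(state.probabilities, state.p0)
        assert np.allclose(ia.rwr_exact(small_network, seeds, gamma=1.0), state.p0)

    def test_two_node_hand_solution(self):
        net = path_network(("A", "B"))
        p = ia.rwr(net, ["A"], gamma=0.5).probabilities
        assert p["A"] == pytest.approx(2.0 / 3.0, abs=1e-10)
        assert p["B"] == pytest.approx(1.0 / 3.0, abs=1e-10)

    def test_triangle_symmetry(self):
        net = path_network(("A", "B"), ("B", "C"), ("A", "C"))
        for gamma in (0.3, 0.7, 0.95):
            p = ia.rwr(net, ["A"], gamma=gamma).probabilities
            assert p["B"] == pytest.approx(p["C"], abs=1e-12)

    def test_star_automorphism_symmetry(self):
        net = path_network(("HUB", "L1"), ("HUB", "L2"), ("HUB", "L3"))
        p = ia.rwr(net, ["HUB"], gamma=0.6).probabilities
        assert p["L1"] == pytest.approx(p["L2"], abs=1e-12)
        assert p["L2"] == pytest.approx(p["L3"], abs=1e-12)

    def test_conservation_and_oracle_equivalence(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(20, 120))
            g = nx.barabasi_albert_graph(n, 2, seed=seed)
            net = ia.PPINetwork.from_graph(g)
            seeds = list(rng.choice(net.nodes, size=3, replace=False))
            gamma = float(rng.uniform(0.2, 0.9))
            state = ia.rwr(net, seeds, gamma=gamma)
            assert state.max_mass_error <= 1e-12
            exact = ia.rwr_exact(net, seeds, gamma=gamma)
            assert np.abs(state.probabilities - exact).max() <= 1e-8
            assert exact.sum() == pytest.approx(1.0, abs=1e-10)

    def test_raw_one_seeding_only_rescales(self):
        """A restart vector of raw ones equals the normalized one up to scale."""
        net = path_network(("A", "B"), ("B", "C"), ("C", "D"), ("B", "D"))
        seeds = ["A", "C"]
        normalized = ia.rwr_exact(net, seeds, gamma=0.7)
        w = net.w.toarray()
        p0_raw = np.array([1.0 if g in seeds else 0.0 for g in net.nodes])
        raw = np.linalg.solve(np.eye(net.n) - 0.3 * w, 0.7 * p0_raw)
        ratio = raw / normalized.to_numpy()
        assert np.allclose(ratio, len(seeds))

    def test_seed_mass_monotone_in_gamma(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            g = nx.barabasi_albert_graph(int(rng.integers(30, 100)), 2, seed=seed)
            net = ia.PPINetwork.from_graph(g)
            seeds = list(rng.choice(net.nodes, size=2, replace=False))
            masses = [
                float(ia.rwr(net, seeds, gamma=gamma).probabilities[seeds].sum())
                for gamma in (0.1, 0.3, 0.5, 0.7, 0.9)
            ]
            assert all(b >= a - 1e-9 for a, b in zip(masses, masses[1:]))

    def test_non_convergence_reports_residual(self, small_network):
        with pytest.raises(RuntimeError, match="residual"):
            ia.rwr(small_network, list(small_network.nodes[:2]), gamma=0.01,
                   tol=1e-14, max_iter=2)

    def test_bad_inputs(self, small_network):
        with pytest.raises(ValueError):
            ia.rwr(small_network, [], gamma=0.5)
        with pytest.raises(ValueError):
            ia.rwr(small_network, list(small_network.nodes[:1]), gamma=0.0)
        with pytest.raises(KeyError):
            ia.rwr(small_network, ["NOT_A_NODE"], gamma=0.5)


class TestTopFraction:
    def test_ceil_counts(self, rng):
        probs = pd.Series(rng.uniform(size=200), index=[f"G{i:04d}" for i in range(200)])
        assert len(ia.top_fraction(probs, 0.01)) == 2
        assert len(ia.top_fraction(probs, 1.0)) == 200

    def test_tie_at_cutoff_prefers_smaller_symbol(self):
        probs = pd.Series({"GB": 0.5, "GA": 0.5, "GC": 0.1})
        assert ia.top_fraction(probs, 1 / 3) == ["GA"]


class TestIntegrateShared:
    def test_intersection_and_identity(self):
        assert ia.integrate_shared([{"A", "B"}, {"B", "C"}]) == {"B"}
        assert ia.integrate_shared([{"A", "B"}]) == {"A", "B"}

    def test_disjoint_sets_error_and_relaxation(self):
        with pytest.raises(ValueError, match="min_conditions"):
            ia.integrate_shared([{"A"}, {"B"}])
        assert ia.integrate_shared([{"A"}, {"B"}], min_conditions=1) == {"A", "B"}
        assert ia.integrate_shared([{"A", "B"}, {"B"}, {"B", "C"}],
                                   min_conditions=2) == {"B"}


class TestTwoStage:
    def test_output_table_contract(self, small_network):
        seeds = list(small_network.nodes[:5])
        table, candidates = ia.two_stage_prioritize(small_network, seeds,
                                                    gamma=0.7, fraction=0.05)
        assert set(seeds) <= set(table["gene"])  # seeds retain probability mass
        assert table["percentile"].iloc[0] == pytest.approx(1 / small_network.n)
        assert len(candidates) == math.ceil(0.05 * small_network.n)
        assert (table["percentile"] > 0).all() and (table["percentile"] <= 1).all()
        assert table["probability"].is_monotonic_decreasing

    def test_planted_clique_members_recovered(self):
        hits = 0
        for seed in range(10):
            drivers = [f"G{i:04d}" for i in range(10)]
            g = ia.generate_network(2000, 3, drivers=drivers, seed=seed)
            net = ia.PPINetwork.from_graph(g)
            table, _ = ia.two_stage_prioritize(net, drivers[:3], fraction=0.05)
            rank = table.set_index("gene")["percentile"]
            hits += all(rank[d] <= 0.05 for d in drivers[3:])
        assert hits >= 9


class TestDrugMapping:
    def test_known_inhibitor_pair_is_mapped(self):
        table = pd.DataFrame({"gene": ["SRC", "FYN", "ZZZ"]})
        drugs = pd.DataFrame({"gene": ["SRC", "SRC", "FYN"],
                              "compound": ["DASATINIB", "BOSUTINIB", "DASATINIB"]})
        out = ia.map_drug_targets(table, drugs)
        assert list(out["gene"]) == ["SRC", "FYN"]  # candidate order preserved
        assert out.loc[0, "compounds"] == ["BOSUTINIB", "DASATINIB"]
        kept = ia.map_drug_targets(table, drugs, keep_unmatched=True)
        assert list(kept["gene"]) == ["SRC", "FYN", "ZZZ"]
        assert kept.loc[2, "compounds"] == []

    def test_empty_and_malformed(self):
        drugs = pd.DataFrame({"gene": ["SRC"], "compound": ["DASATINIB"]})
        assert ia.map_drug_targets([], drugs).empty
        with pytest.raises(ValueError):
            ia.map_drug_targets(["SRC"], pd.DataFrame({"g": [], "c": []}))


def test_pipeline_seeds_are_planted_drivers(small_cohort, small_network):
    """Stage-1 seeds should be dominated by genes carrying both planted effects."""
    res = ia.run_two_stage_pipeline(small_cohort.expression, small_cohort.metadata,
                                    small_network)
    drivers = set(small_cohort.truth["drivers"])
    for seeds in res["per_cancer_seeds"].values():
        assert len(set(seeds) & drivers) / len(seeds) >= 0.5
    assert res["table"].shape[0] == small_network.n
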