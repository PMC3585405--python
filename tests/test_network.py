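import numpy as np
import pandas as pd
import pytest

import eigentrait as et
from eigentrait.network import PrunedNetwork, UNASSIGNED


def _scaled(df):
    return et.autoscale(pd.DataFrame(df))


class TestBuildNetwork:
    def test_identical_features_weight_one(self, rng):
        x = rng.normal(size=20)
        sm = _scaled({"a": x, "b": x.copy()})
        net = et.build_network(sm, 6)
        assert net.weights[0, 1] == pytest.approx(1.0)

    def test_orthogonal_features_weight_zero(self):
        sm = _scaled({"a": [1, -1, 1, -1], "b": [1, 1, -1, -1]})
        net = et.build_network(sm, 2)
        assert net.weights[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negative_half_correlation_squares(self):
        # x, y constructed with exactly r = -0.5
        x = np.array([1.0, -1.0, 0.0, 0.0])
        y = np.array([-1.0, 0.0, 1.0, 0.0])
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(-0.5)
        sm = _scaled({"a": x, "b": y})
        net = et.build_network(sm, 2)
        assert net.weights[0, 1] == pytest.approx(0.25)

    def test_zero_variance_node_rejected(self):
        sm = et.ScaledMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0],
                                           "b": [5.0, 5.0, 5.0]}), "autoscale")
        with pytest.raises(ValueError, match="zero-variance"):
            et.build_network(sm, 2)

    def test_unsigned_symmetry_under_column_negation(self, rng):
        X = rng.normal(size=(30, 6))
        sm1 = _scaled(pd.DataFrame(X, columns=list("abcdef")))
        X2 = X.copy()
        X2[:, 2] *= -1
        sm2 = _scaled(pd.DataFrame(X2, columns=list("abcdef")))
        n1, n2 = et.build_network(sm1, 4), et.build_network(sm2, 4)
        assert np.allclose(n1.weights, n2.weights)


class TestSoftThreshold:
    def test_block_structured_selection_deterministic(self, rng):
        cfg = et.SimConfig(seed=21, n_lines=100, n_snps=50, n_features=150,
                           module_sizes=(40, 30, 25, 20, 15))
        _, ft, _, _ = et.simulate_cohort(cfg)
        sm = et.autoscale(ft)
        beta1, rep1 = et.pick_soft_threshold(sm)
        beta2, _ = et.pick_soft_threshold(sm)
        assert beta1 == beta2 >= 1
        assert set(rep1.columns) == {"beta", "sft_r2", "mean_connectivity"}

    def test_single_module_smoke(self, rng):
        z = rng.normal(size=50)
        X = pd.DataFrame({f"f{i}": z + 0.3 * rng.normal(size=50) for i in range(10)})
        beta, report = et.pick_soft_threshold(et.autoscale(X))
        assert beta >= 1 and len(report) == 20


class TestDetectModules:
    def test_two_tight_blocks_recovered_exactly(self, rng):
        z1, z2 = rng.normal(size=(2, 200))
        cols = {}
        for i in range(10):
            cols[f"a{i}"] = z1 + 0.18 * rng.normal(size=200)  # r ~ 0.97
        for i in range(10):
            cols[f"b{i}"] = z2 + 0.18 * rng.normal(size=200)
        sm = _scaled(cols)
        part = et.detect_modules(et.build_network(sm, 6), min_module_size=10)
        assert len(part.modules) == 2
        blocks = {frozenset(part.members(c)) for c in part.modules}
        assert blocks == {frozenset(f"a{i}" for i in range(10)),
                          frozenset(f"b{i}" for i in range(10))}

    def test_pure_noise_all_grey(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 80)),
                         columns=[f"f{i:02d}" for i in range(80)])
        part = et.detect_modules(et.build_network(_scaled(X), 6),
                                 min_module_size=10)
        assert set(part.labels) == {UNASSIGNED}

    def test_sample_permutation_invariance(self, rng):
        cfg = et.SimConfig(seed=5, n_lines=80, n_snps=50, n_features=120,
                           module_sizes=(40, 30, 20))
        _, ft, _, _ = et.simulate_cohort(cfg)
        sm = et.autoscale(ft)
        part1 = et.detect_modules(et.build_network(sm, 6))
        perm = rng.permutation(sm.values.index)
        sm2 = et.ScaledMatrix(sm.values.loc[perm], "autoscale")
        part2 = et.detect_modules(et.build_network(sm2, 6))
        pd.testing.assert_series_equal(part1.labels, part2.labels)

    def test_min_module_size_validation(self, rng):
        sm = _scaled(pd.DataFrame(rng.normal(size=(10, 4))))
        with pytest.raises(ValueError):
            et.detect_modules(et.build_network(sm, 2), min_module_size=1)

    def test_color_order_follows_module_size(self, factor_network):
        _, _, part = factor_network
        sizes = part.sizes().drop(UNASSIGNED, errors="ignore")
        assert list(sizes.index[:3]) == ["turquoise", "blue", "brown"]
        assert sizes.is_monotonic_decreasing


class TestModuleEigenvalues:
    def test_single_feature_module(self, rng):
        x = rng.normal(size=30)
        sm = _scaled({"solo": x, "noise": rng.normal(size=30)})
        part = et.ModulePartition(pd.Series({"solo": "turquoise",
                                             "noise": UNASSIGNED}))
        me = et.module_eigenvalues(sm, part)
        assert me.pve["turquoise"] == pytest.approx(1.0)
        assert np.allclose(me.scores.loc["turquoise"],
                           sm.values["solo"].to_numpy())

    def test_identical_features_share_profile(self, rng):
        x = rng.normal(size=25)
        sm = _scaled({f"f{i}": x for i in range(5)})
        part = et.ModulePartition(pd.Series("turquoise", index=sm.values.columns))
        me = et.module_eigenvalues(sm, part)
        assert me.pve["turquoise"] == pytest.approx(1.0)
        shared = sm.values.iloc[:, 0].to_numpy()
        assert np.allclose(me.scores.loc["turquoise"], shared, atol=1e-8)

    def test_unit_variance_and_sign_alignment(self, factor_network):
        sm, _, part = factor_network
        me = et.module_eigenvalues(sm, part)
        for color in part.modules:
            row = me.scores.loc[color].to_numpy()
            assert row.std(ddof=1) == pytest.approx(1.0)
            mean_profile = sm.values[part.members(color)].mean(axis=1)
            assert np.corrcoef(row, mean_profile)[0, 1] >= 0

    def test_recovers_simulated_latent(self, factor_cohort, factor_network):
        _, _, _, _, truth = factor_cohort
        sm, _, part = factor_network
        me = et.module_eigenvalues(sm, part)
        color = part.modules[0]  # largest detected module
        true_mod = int(truth.module_membership[part.members(color)].mode()[0])
        latent = truth.latents.iloc[:, true_mod]
        r = np.corrcoef(me.scores.loc[color], latent)[0, 1]
        assert abs(r) > 0.95

    def test_matches_svd_oracle(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 6)),
                         columns=[f"f{i}" for i in range(6)])
        sm = et.autoscale(X)
        part = et.ModulePartition(pd.Series("turquoise", index=sm.values.columns))
        me = et.module_eigenvalues(sm, part)
        M = sm.values.to_numpy()
        M = M - M.mean(axis=0)
        u, s, vt = np.linalg.svd(M)  # independent decomposition
        pc1 = u[:, 0] / u[:, 0].std(ddof=1)
        got = me.scores.loc["turquoise"].to_numpy()
        assert min(np.max(np.abs(got - pc1)), np.max(np.abs(got + pc1))) < 1e-8

    def test_empty_module_errors(self, rng):
        sm = _scaled(pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"]))
        part = et.ModulePartition(pd.Series({"c": "turquoise"}))
        with pytest.raises(ValueError):
            et.module_eigenvalues(sm, part)


def _toy_network(weights_by_pair, nodes):
    n = len(nodes)
    w = np.eye(n)
    for (i, j), v in weights_by_pair.items():
        w[i, j] = w[j, i] = v
    return et.CorrelationNetwork(list(nodes), w, 1.0)


class TestPruning:
    def test_equal_weights_strict_threshold_empty(self):
        pairs = {(i, j): 0.5 for i in range(4) for j in range(i + 1, 4)}
        pn = et.prune_at_sd(_toy_network(pairs, "abcd"), 4)
        assert pn.n_edges == 0 and pn.n_nodes == 0

    def test_low_k_keeps_complete_graph(self, rng):
        vals = rng.uniform(0.3, 0.9, size=10)
        pairs = dict(zip([(i, j) for i in range(5) for j in range(i + 1, 5)], vals))
        pn = et.prune_at_sd(_toy_network(pairs, "abcde"), -10)
        assert pn.n_edges == 5 * 4 // 2

    def test_five_node_hand_oracle(self):
        import statistics
        weights = [1.0, 0.9, 0.8, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        pair_list = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        pairs = dict(zip(pair_list, weights))
        t = statistics.fmean(weights) + statistics.pstdev(weights)  # hand oracle
        expected = {pair for pair, w in pairs.items() if w > t}
        pn = et.prune_at_sd(_toy_network(pairs, "abcde"), 1)
        nodes = list("abcde")
        got = {(nodes.index(s), nodes.index(t_)) for s, t_ in pn.edge_set()}
        assert got == expected == {(0, 1), (0, 2), (0, 3)}

    def test_nestedness_across_k(self, factor_network):
        _, net, _ = factor_network
        e1 = et.prune_at_sd(net, 1).edge_set()
        e4 = et.prune_at_sd(net, 4).edge_set()
        e6 = et.prune_at_sd(net, 6).edge_set()
        assert e6 <= e4 <= e1

    def test_components_counted(self):
        pairs = {(0, 1): 0.9, (2, 3): 0.9, (0, 4): 0.05}
        pn = et.prune_at_sd(_toy_network(pairs, "abcde"), 0)
        assert pn.n_components == 2  # a-b and c-d; the weak a-e edge pruned


class TestNetworkSummary:
    def test_counts_to_percentage(self):
        labels = pd.Series(["turquoise"] * 4102 + [UNASSIGNED] * (8710 - 4102),
                           index=[f"f{i}" for i in range(8710)])
        part = et.ModulePartition(labels)
        pn = PrunedNetwork(pd.DataFrame(columns=["source", "target", "weight"]),
                           4.0, 0.5, [f"f{i}" for i in range(4102)], 101)
        table = et.network_summary(part, {4.0: pn})
        assert table.loc[0, "pct_of_detected"] == 47.1
        assert table.loc[0, "nodes"] == 4102

    def test_full_retention_is_100(self):
        labels = pd.Series(["turquoise"] * 10, index=[f"f{i}" for i in range(10)])
        pn = PrunedNetwork(pd.DataFrame(columns=["source", "target", "weight"]),
                           1.0, 0.1, [f"f{i}" for i in range(10)], 1)
        table = et.network_summary(et.ModulePartition(labels), {1.0: pn})
        assert table.loc[0, "pct_of_detected"] == 100.0

    def test_node_counts_monotone_in_k(self, factor_network):
        _, net, part = factor_network
        pruned = {k: et.prune_at_sd(net, k) for k in (1, 4, 6)}
        table = et.network_summary(part, pruned).set_index("k_sd")
        assert table.loc[6, "nodes"] <= table.loc[4, "nodes"] <= table.loc[1, "nodes"]


class TestExports:
    def test_empty_network_header_only(self, tmp_path):
        pn = PrunedNetwork(pd.DataFrame(columns=["source", "target", "weight"]),
                           4.0, 0.5, [], 0)
        paths = et.export_edges(pn, tmp_path / "net")
        assert open(paths["edges"]).read() == "source\ttarget\tweight\n"
        assert open(paths["sif"]).read() == ""

    def test_three_edge_roundtrip(self, tmp_path):
        edges = pd.DataFrame({"source": ["a", "a", "b"],
                              "target": ["b", "c", "c"],
                              "weight": [0.9, 0.8123456, 0.7]})
        pn = PrunedNetwork(edges, 1.0, 0.5, ["a", "b", "c"], 1)
        paths = et.export_edges(pn, tmp_path / "net")
        lines = open(paths["edges"]).read().splitlines()
        assert len(lines) == 4 and lines[2].endswith("0.812346")  # 6 decimals
        back = pd.read_csv(paths["edges"], sep="\t")
        assert {tuple(sorted((s, t))) for s, t in zip(back["source"], back["target"])} \
            == pn.edge_set()


class TestGuiltByAssociation:
    def test_single_annotation_propagates_with_edge_score(self):
        part = et.ModulePartition(pd.Series({"A": "orange", "B": "orange"}))
        edges = pd.DataFrame({"source": ["A"], "target": ["B"], "weight": [0.9]})
        pn = PrunedNetwork(edges, 4.0, 0.5, ["A", "B"], 1)
        out = et.annotate_by_association(part, pn, {"A": "tyramine"})
        assert out.loc[0, "node"] == "B"
        assert out.loc[0, "annotation"] == "tyramine-associated"
        assert out.loc[0, "score"] == 0.9

    def test_isolated_annotated_node_scores_zero(self):
        part = et.ModulePartition(pd.Series({"A": "orange", "B": "orange"}))
        pn = PrunedNetwork(pd.DataFrame(columns=["source", "target", "weight"]),
                           6.0, 0.99, [], 0)
        out = et.annotate_by_association(part, pn, {"A": "tyramine"})
        assert out.loc[0, "score"] == 0.0

    def test_two_annotations_ranked_by_weight(self):
        # 6-node toy, exhaustive expectation
        labels = pd.Series({"A": "orange", "B": "orange", "C": "orange",
                            "D": "blue", "E": "blue", "F": UNASSIGNED})
        part = et.ModulePartition(labels)
        edges = pd.DataFrame({"source": ["A", "B", "D"],
                              "target": ["C", "C", "E"],
                              "weight": [0.6, 0.8, 0.9]})
        pn = PrunedNetwork(edges, 1.0, 0.2, ["A", "B", "C", "D", "E"], 2)
        out = et.annotate_by_association(
            part, pn, {"A": "tyramine", "B": "coumaroyltyramine", "D": "zein"})
        c_rows = out[out["node"] == "C"]
        assert list(c_rows["annotation"]) == ["coumaroyltyramine-associated",
                                              "tyramine-associated"]
        assert list(c_rows["score"]) == [0.8, 0.6]
        e_rows = out[out["node"] == "E"]
        assert list(e_rows["annotation"]) == ["zein-associated"]
        assert "F" not in set(out["node"])  # grey nodes receive nothing

    def test_requires_an_annotation(self):
        part = et.ModulePartition(pd.Series({"A": "orange"}))
        pn = PrunedNetwork(pd.DataFrame(columns=["source", "target", "weight"]),
                           1.0, 0.2, [], 0)
        with pytest.raises(ValueError):
            et.annotate_by_association(part, pn, {})


def test_partition_unchanged_when_feature_negated(rng):
    cfg = et.SimConfig(seed=9, n_lines=100, n_snps=50, n_features=100,
                       module_sizes=(30, 25, 15))
    _, ft, _, _ = et.simulate_cohort(cfg)
    sm = et.autoscale(ft)
    part1 = et.detect_modules(et.build_network(sm, 6))
    flipped = sm.values.copy()
    flipped.iloc[:, 0] *= -1
    part2 = et.detect_modules(et.build_network(
        et.ScaledMatrix(flipped, "autoscale"), 6))
    pd.testing.assert_series_equal(part1.labels, part2.labels)
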