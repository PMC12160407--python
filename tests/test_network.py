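"""Network topology: closed forms, brute-force BFS oracles, group statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from culturemap.network import (
    HubCriteria,
    InteractionNetwork,
    avg_shortest_path_length,
    betweenness,
    centrality_group_test,
    centrality_pca,
    classify_hubs,
    closeness,
    compute_profiles,
    degree,
    edge_sharing_classification,
    infer_network,
    nearest_hub_distance,
    neighborhood_connectivity,
    pearson_chi2,
    radiality,
)

from conftest import (
    adjacency,
    oracle_avg_path_length,
    oracle_betweenness,
    oracle_closeness,
    oracle_nearest_hub,
    oracle_neighborhood_connectivity,
    oracle_radiality,
    random_network,
)


def _star(n_leaves=4):
    net = InteractionNetwork()
    for i in range(n_leaves):
        net.add_edge("c", f"l{i}", "+", 0.5)
    return net


def _path3():
    net = InteractionNetwork()
    net.add_edge("a", "b", "+", 0.5)
    net.add_edge("b", "c", "+", 0.5)
    return net


def _k3():
    net = InteractionNetwork()
    for a, b in (("a", "b"), ("b", "c"), ("a", "c")):
        net.add_edge(a, b, "+", 0.5)
    return net


class TestNetworkContainer:
    def test_self_loops_and_duplicates_rejected(self):
        net = InteractionNetwork()
        with pytest.raises(ValueError):
            net.add_edge("a", "a", "+", 0.5)
        net.add_edge("a", "b", "+", 0.5)
        with pytest.raises(ValueError):
            net.add_edge("b", "a", "-", 0.3)

    def test_bad_sign_and_weight_rejected(self):
        net = InteractionNetwork()
        with pytest.raises(ValueError):
            net.add_edge("a", "b", "x", 0.5)
        with pytest.raises(ValueError):
            net.add_edge("a", "b", "+", 0.0)
        with pytest.raises(ValueError):
            net.add_edge("a", "b", "+", 1.5)


class TestClosedForms:
    def test_star_center(self):
        net = _star()
        assert degree(net)["c"] == 4
        assert betweenness(net)["c"] == 1.0
        assert closeness(net)["c"] == 1.0
        assert radiality(net)["c"] == 2.0
        assert neighborhood_connectivity(net)["c"] == 1.0
        assert avg_shortest_path_length(net)["c"] == 1.0

    def test_star_leaf(self):
        net = _star()
        assert neighborhood_connectivity(net)["l0"] == 4.0
        assert avg_shortest_path_length(net)["l0"] == 1.75  # (1 + 2*3)/4

    def test_path_of_three(self):
        net = _path3()
        assert betweenness(net)["b"] == 1.0
        assert closeness(net)["b"] == 1.0
        assert closeness(net)["a"] == pytest.approx(2 / 3)

    def test_triangle(self):
        net = _k3()
        assert all(v == 1.0 for v in radiality(net).values())
        assert all(v == 1.0 for v in avg_shortest_path_length(net).values())
        assert all(v == 0.0 for v in betweenness(net).values())

    def test_isolated_node_conventions(self):
        net = _path3()
        net.add_node("z")
        assert closeness(net)["z"] == 0.0
        assert radiality(net)["z"] == 0.0
        assert math.isnan(neighborhood_connectivity(net)["z"])
        assert math.isnan(avg_shortest_path_length(net)["z"])

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            degree(InteractionNetwork())


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_measures_match_bfs_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        net = random_network(rng, n, p=float(rng.uniform(0.08, 0.3)))
        adj = adjacency(net)
        for ours, oracle in [
            (betweenness(net), oracle_betweenness(adj)),
            (closeness(net), oracle_closeness(adj)),
            (radiality(net), oracle_radiality(adj)),
            (neighborhood_connectivity(net), oracle_neighborhood_connectivity(adj)),
            (avg_shortest_path_length(net), oracle_avg_path_length(adj)),
        ]:
            for v in adj:
                if math.isnan(oracle[v]):
                    assert math.isnan(ours[v])
                else:
                    assert ours[v] == pytest.approx(oracle[v], abs=1e-10), v

    @pytest.mark.parametrize("seed", range(4))
    def test_nearest_hub_matches_single_source_minimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        net = random_network(rng, 20, p=0.12)
        adj = adjacency(net)
        hubs = [v for v in list(adj)[:5]]
        ours = nearest_hub_distance(net, hubs)
        oracle = oracle_nearest_hub(adj, hubs)
        for v in adj:
            if math.isnan(oracle[v]):
                assert math.isnan(ours[v])
            else:
                assert ours[v] == oracle[v]


class TestHubs:
    def test_joint_threshold_classification(self):
        profiles = pd.DataFrame(
            {
                "degree": [8, 7, 9],
                "betweenness": [0.15, 0.5, 0.1],
                "closeness": [0.35, 0.5, 0.5],
            },
            index=["hub", "deg_boundary", "btw_boundary"],
        )
        assert classify_hubs(profiles) == {"hub"}

    def test_wheel_plus_pendant_hub_set_matches_measure_recomputation(self):
        # 10-spoke wheel with a pendant on one rim node: the center is the
        # only node that clears all three thresholds simultaneously
        net = InteractionNetwork()
        rim = [f"r{i}" for i in range(10)]
        for i, v in enumerate(rim):
            net.add_edge("hub", v, "+", 0.5)
            net.add_edge(v, rim[(i + 1) % 10], "+", 0.5)
        net.add_edge("r0", "pendant", "+", 0.5)
        profiles = compute_profiles(net)
        adj = adjacency(net)
        btw, clo = oracle_betweenness(adj), oracle_closeness(adj)
        expected = {
            v
            for v in adj
            if len(adj[v]) > 7 and btw[v] > 0.1 and clo[v] > 0.3
        }
        assert expected == {"hub"}
        assert set(profiles.index[profiles.hub]) == expected

    def test_hub_distance_is_zero_iff_hub(self, small_bundle):
        net = InteractionNetwork.from_edges(small_bundle.manifest.edges)
        profiles = compute_profiles(net)
        zero = profiles["nearest_hub_distance"] == 0
        assert (zero == profiles["hub"]).all()

    def test_empty_hub_set_gives_all_unreachable(self):
        net = _path3()
        dist = nearest_hub_distance(net, [])
        assert all(math.isnan(v) for v in dist.values())

    def test_adjacent_to_hub_is_distance_one(self):
        net = _star()
        dist = nearest_hub_distance(net, ["c"])
        assert dist["c"] == 0.0 and dist["l0"] == 1.0

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            HubCriteria(degree_min=0)


class TestEdgeSharing:
    @staticmethod
    def _flagged_net():
        net = InteractionNetwork()
        flags = {"u0": False, "u1": False, "u2": False, "u3": False,
                 "c0": True, "c1": True}
        for n, f in flags.items():
            net.add_node(n, cultured=f)
        # u0 has 3 uncultured and 1 cultured neighbours
        for other in ("u1", "u2", "u3", "c0"):
            net.add_edge("u0", other, "+", 0.5)
        # c1 has exactly 2 of 4 cultured neighbours -> tie
        net.add_edge("c1", "c0", "+", 0.5)
        net.add_edge("c1", "u1", "+", 0.5)
        net.add_edge("c1", "u2", "+", 0.5)
        return net, flags

    def test_majority_and_tie_labels(self):
        net, _ = self._flagged_net()
        per_node, _, _, _ = edge_sharing_classification(net)
        assert per_node.loc["u0", "majority"] == "majority_uncultured"
        # c0 neighbours: u0 and c1 -> exactly half cultured -> tie
        assert per_node.loc["c0", "majority"] == "tie"

    def test_missing_flag_rejected(self):
        net = InteractionNetwork()
        net.add_edge("a", "b", "+", 0.5)
        with pytest.raises(ValueError):
            edge_sharing_classification(net)

    def test_chi2_closed_form_on_toy_table(self):
        table = np.array([[10, 2], [3, 9]], dtype=float)
        chi2, p = pearson_chi2(table)
        a, b, c, d = table.ravel()
        n = table.sum()
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert chi2 == pytest.approx(closed)  # = 8.2238
        assert chi2 == pytest.approx(8.2238, abs=1e-4)
        assert p == pytest.approx(0.00414, abs=1e-5)


class TestGroupTests:
    def test_identical_groups_are_null(self):
        net = random_network(np.random.default_rng(5), 16, 0.25)
        profiles = compute_profiles(net)
        # mirror the same nodes into both groups via duplicated values
        flags = {v: (i % 2 == 0) for i, v in enumerate(profiles.index)}
        profiles2 = profiles.copy()
        half = [v for v, f in flags.items() if f]
        for measure in ("closeness", "radiality"):
            vals = profiles2[measure]
            x = vals[[v for v in vals.index if flags[v]]]
            y = x.copy()
            from culturemap.fractions import mann_whitney_u

            _, p = mann_whitney_u(x, y)
            assert p >= 0.99

    def test_planted_hub_proximity_bias_is_detected(self):
        from culturemap.synthetic import SimConfig, generate_bundle

        cfg = SimConfig(seed=11, n_network_nodes=160, network_cultured_fraction=0.35,
                        hub_uncultured_bias=1.0, edge_density=0.012, n_hubs=8)
        bundle = generate_bundle(cfg)
        net = InteractionNetwork.from_edges(bundle.manifest.edges)
        flags = {a: bundle.manifest.asvs[a].planted_bin == "cultured"
                 for a in net.graph.nodes}
        net.set_cultured_flags(flags)
        profiles = compute_profiles(net)
        tests = centrality_group_test(profiles, flags)
        assert tests.loc["nearest_hub_distance", "p"] < 0.05
        assert tests.loc["nearest_hub_distance", "n_cultured"] >= 20
        assert tests.loc["nearest_hub_distance", "n_uncultured"] >= 30

    def test_single_group_rejected(self):
        net = _k3()
        profiles = compute_profiles(net)
        with pytest.raises(ValueError):
            centrality_group_test(profiles, {v: True for v in profiles.index})


class TestPCA:
    def test_duplicated_feature_gives_two_thirds_variance(self):
        rng = np.random.default_rng(3)
        f1 = rng.normal(size=50)
        f3 = rng.normal(size=50)
        # orthogonalize so corr(f1, f3) is exactly zero and the correlation
        # matrix eigenvalues are exactly (2, 1, 0)
        f1c = f1 - f1.mean()
        f3 = f3 - f3.mean() - f1c * ((f3 - f3.mean()) @ f1c) / (f1c @ f1c)
        profiles = pd.DataFrame(
            {"degree": f1, "closeness": 2.0 * f1, "radiality": f3}
        )
        _, _, ratio = centrality_pca(profiles, features=["degree", "closeness",
                                                         "radiality"])
        assert ratio[0] == pytest.approx(2 / 3, abs=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        profiles = pd.DataFrame(rng.normal(size=(30, 3)),
                                columns=["degree", "closeness", "radiality"])
        loadings, _, _ = centrality_pca(profiles, features=list(profiles.columns))
        for comp in loadings.columns:
            col = loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.normal(size=(40, 4)),
                                columns=list("abcd"))
        loadings, scores, _ = centrality_pca(profiles, features=list("abcd"))
        Z = (profiles - profiles.mean()) / profiles.std(ddof=1)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.allclose(recon, Z.to_numpy(), atol=1e-10)

    def test_zero_variance_feature_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        profiles = pd.DataFrame(
            {"a": rng.normal(size=20), "b": rng.normal(size=20),
             "c": np.ones(20)}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            loadings, _, _ = centrality_pca(profiles, features=["a", "b", "c"])
        assert "c" not in loadings.index

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            centrality_pca(pd.DataFrame({"a": [1.0, 2.0]}), features=["a"])


class TestInference:
    def test_planted_covariation_is_recovered(self):
        rng = np.random.default_rng(5)
        n = 40
        base = rng.lognormal(0, 1, size=(12, n))
        signal = rng.lognormal(0, 1, size=n)
        base[0] = signal * 3
        base[1] = signal * 2
        counts = pd.DataFrame(
            np.floor(base * 100).astype(int),
            index=[f"A{i}" for i in range(12)],
            columns=[f"S{j}" for j in range(n)],
        )
        net = infer_network(counts, min_obs=20, alpha=0.05, n_perm=2000, seed=7)
        edge = net.graph.get_edge_data("A0", "A1")
        assert edge is not None and edge["sign"] == "+"
        assert edge["weight"] > 0.9

    def test_null_false_edge_rate_within_alpha(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.poisson(50, size=(15, 40)),
            index=[f"N{i}" for i in range(15)],
            columns=[f"S{j}" for j in range(40)],
        )
        net = infer_network(counts, min_obs=20, alpha=0.05, n_perm=1000, seed=9)
        n_pairs = 15 * 14 // 2
        from scipy.stats import binom

        upper = binom.ppf(0.975, n_pairs, 0.05)
        assert net.n_edges <= upper

    def test_argument_validation(self):
        counts = pd.DataFrame(np.ones((4, 10), dtype=int))
        with pytest.raises(ValueError):
            infer_network(counts, min_obs=11)
        with pytest.raises(ValueError):
            infer_network(counts, min_obs=5, n_perm=0)
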