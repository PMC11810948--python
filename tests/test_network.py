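import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import traitnet as tn
from traitnet.catalog import codes_in_category
from traitnet.errors import TraitnetError
from traitnet.network import MIN_PAIRS, NetworkMetrics, hub_traits

from _oracles import brute_force_max_modularity, modularity_from_adjacency
from conftest import random_connected_graph


class TestSpearmanMatrix:
    def test_hand_example_without_ties(self):
        # d^2 = (0,1,1,0,1)... rho = 1 - 6*4/(5*24) = 0.8
        m = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 3, 2, 5, 4]})
        corr = tn.spearman_matrix(m)
        assert corr.rho.loc["x", "y"] == pytest.approx(0.8)
        assert corr.n_pairs.loc["x", "y"] == 5

    def test_perfect_monotone_pairs(self):
        x = np.arange(12, dtype=float)
        m = pd.DataFrame({"x": x, "up": np.exp(x), "down": -x})
        corr = tn.spearman_matrix(m)
        assert corr.rho.loc["x", "up"] == pytest.approx(1.0)
        assert corr.rho.loc["x", "down"] == pytest.approx(-1.0)
        assert corr.p.loc["x", "up"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_permutation_p_for_tiny_n(self):
        m = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [1, 3, 2, 5, 4]})
        p = tn.spearman_matrix(m).p.loc["x", "y"]
        # exact tail: fraction of 5! orderings with |rho| >= 0.8
        count = 0
        for perm in itertools.permutations([1, 3, 2, 5, 4]):
            rho = 1 - 6 * sum((a - b) ** 2 for a, b in zip([1, 2, 3, 4, 5], perm)) / (5 * 24)
            count += abs(rho) >= 0.8 - 1e-12
        assert p == pytest.approx(count / 120)

    def test_insufficient_pairs_flagged(self):
        m = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 1, 4, 3]})
        corr = tn.spearman_matrix(m)
        assert np.isnan(corr.rho.loc["x", "y"])

    def test_pairwise_deletion(self):
        x = np.arange(20, dtype=float)
        y = x.copy()
        y[3] = np.nan
        corr = tn.spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert corr.n_pairs.loc["x", "y"] == 19
        assert corr.rho.loc["x", "y"] == pytest.approx(1.0)


class TestBinarize:
    def _corr(self, rho, p):
        idx = ["a", "b"]
        full = lambda v: pd.DataFrame([[1.0, v], [v, 1.0]], index=idx, columns=idx)
        return tn.CorrelationMatrices(
            full(rho), pd.DataFrame([[0.0, p], [p, 0.0]], index=idx, columns=idx),
            pd.DataFrame(30, index=idx, columns=idx),
        )

    @pytest.mark.parametrize(
        "rho,p,edge",
        [
            (0.5, 0.01, True),
            (0.20, 0.001, False),  # threshold is strict
            (-0.6, 0.001, True),  # absolute value
            (0.5, 0.05, False),  # p threshold strict too
            (0.19, 0.01, False),
        ],
    )
    def test_strict_threshold_rule(self, rho, p, edge):
        net = tn.binarize(self._corr(rho, p))
        assert bool(net.adjacency.loc["a", "b"]) is edge

    def test_missing_correlation_never_an_edge(self):
        net = tn.binarize(self._corr(np.nan, np.nan))
        assert net.adjacency.loc["a", "b"] == 0

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(TraitnetError):
            tn.binarize(self._corr(0.5, 0.01), r_threshold=0.0)


class TestCommunityDetection:
    def test_complete_graph_single_community_zero_q(self):
        q, part = tn.detect_communities(nx.complete_graph(4))
        assert q == pytest.approx(0.0)
        assert len(part) == 1

    def test_two_disjoint_cliques_recovered_with_q_half(self):
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        q, part = tn.detect_communities(G)
        assert q == pytest.approx(0.5)
        assert sorted(map(sorted, part)) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_brute_force(self, seed):
        G = random_connected_graph(seed)
        q, _ = tn.detect_communities(G)
        adj = nx.to_numpy_array(G)
        q_oracle, _ = brute_force_max_modularity(adj)
        assert q == pytest.approx(q_oracle, abs=1e-9)

    def test_greedy_path_recovers_three_planted_cliques(self):
        # 15 nodes > exact threshold: exercises the greedy search proper
        G = nx.Graph()
        blocks = [range(0, 5), range(5, 10), range(10, 15)]
        for block in blocks:
            G.add_edges_from(itertools.combinations(block, 2))
        G.add_edge(0, 5)
        G.add_edge(5, 10)  # sparse bridges
        q, part = tn.greedy_modularity(G)
        assert sorted(map(sorted, part)) == [list(b) for b in blocks]
        labels = np.zeros(15, dtype=int)
        for i, c in enumerate(part):
            for u in c:
                labels[u] = i
        assert q == pytest.approx(modularity_from_adjacency(nx.to_numpy_array(G), labels))

    def test_greedy_never_below_singleton_partition(self):
        for seed in range(5):
            G = nx.gnp_random_graph(12, 0.3, seed=seed)
            if G.number_of_edges() == 0:
                continue
            q, _ = tn.greedy_modularity(G)
            singletons = [{n} for n in G.nodes()]
            assert q >= nx.algorithms.community.modularity(G, singletons) - 1e-12


class TestNetworkMetrics:
    def _net_from_graph(self, G, codes):
        adj = pd.DataFrame(0, index=codes, columns=codes)
        for u, v in G.edges():
            adj.loc[codes[u], codes[v]] = adj.loc[codes[v], codes[u]] = 1
        cats = {c: "economic" for c in codes}
        ones = pd.DataFrame(1.0, index=codes, columns=codes)
        return tn.TraitNetwork(adj, cats, ones, ones * 0.0, 0.2, 0.05)

    def test_complete_graph_density_and_path_length(self):
        codes = list("abcd")
        m = tn.network_metrics(self._net_from_graph(nx.complete_graph(4), codes))
        assert m.edge_density == pytest.approx(1.0)
        assert m.average_path_length == pytest.approx(1.0)
        assert m.connected

    def test_degree_sum_is_twice_edges(self, small_table):
        net, m = tn.build_network(small_table)
        assert sum(m.degree.values()) == 2 * m.n_edges

    def test_empty_network_flagged(self, codes):
        adj = pd.DataFrame(0, index=codes, columns=codes)
        ones = pd.DataFrame(1.0, index=codes, columns=codes)
        net = tn.TraitNetwork(adj, {c: "economic" for c in codes}, ones, ones, 0.2, 0.05)
        with pytest.warns(UserWarning):
            m = tn.network_metrics(net)
        assert m.edge_density == 0.0
        assert m.modularity == 0.0
        assert np.isnan(m.average_path_length)
        assert len(set(m.modules.values())) == 26

    def test_disconnected_average_path_over_connected_pairs(self):
        codes = list("abcdefgh")
        G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        m = tn.network_metrics(self._net_from_graph(G, codes))
        assert not m.connected
        assert m.average_path_length == pytest.approx(1.0)  # within-clique pairs only
        assert any("disconnected" in f for f in m.flags)

    def test_block_structured_correlation_gives_planted_density(self):
        # two 4-trait blocks of exact monotone relationships
        rng = np.random.default_rng(0)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        m = pd.DataFrame({f"x{i}": (i + 1) * x for i in range(4)} | {f"y{i}": (i + 1) * y for i in range(4)})
        net, metrics = tn.build_network(m)
        within = 2 * 6  # both blocks complete
        assert metrics.n_edges >= within
        planted_fraction = within / (8 * 7 / 2)
        assert metrics.edge_density >= planted_fraction


class TestRelativeImportance:
    def test_equal_degrees_give_uniform_importance(self, codes):
        cats = tn.catalog.category_of()
        m = NetworkMetrics(
            degree={c: 4 for c in codes}, n_edges=52, edge_density=0.16,
            modularity=0.0, modules={}, average_path_length=1.0, connected=True,
        )
        ri = tn.relative_importance(m, cats)
        assert ri["economic"] == pytest.approx(1 / 26)
        assert ri["nutrient"] == pytest.approx(1 / 26)
        assert ri["defensive"] == pytest.approx(1 / 26)

    def test_single_hub_concentrates_importance(self, codes):
        cats = tn.catalog.category_of()
        economic = codes_in_category("economic")
        deg = {c: 0 for c in codes}
        deg[economic[0]] = 10
        m = NetworkMetrics(
            degree=deg, n_edges=5, edge_density=0.01, modularity=0.0,
            modules={}, average_path_length=1.0, connected=False,
        )
        ri = tn.relative_importance(m, cats)
        assert ri["economic"] == pytest.approx((10 / 7) / 10)
        assert ri["nutrient"] == 0.0

    def test_scale_invariance(self, codes):
        cats = tn.catalog.category_of()
        rng = np.random.default_rng(1)
        deg = {c: int(d) for c, d in zip(codes, rng.integers(0, 10, 26))}
        mk = lambda d: NetworkMetrics(
            degree=d, n_edges=1, edge_density=0.1, modularity=0.0, modules={},
            average_path_length=1.0, connected=False,
        )
        ri1 = tn.relative_importance(mk(deg), cats)
        ri2 = tn.relative_importance(mk({c: 2 * d for c, d in deg.items()}), cats)
        for cat in ri1:
            assert ri1[cat] == pytest.approx(ri2[cat])

    def test_all_zero_degrees_warn(self, codes):
        cats = tn.catalog.category_of()
        m = NetworkMetrics(
            degree={c: 0 for c in codes}, n_edges=0, edge_density=0.0,
            modularity=0.0, modules={}, average_path_length=np.nan, connected=False,
        )
        with pytest.warns(UserWarning):
            ri = tn.relative_importance(m, cats)
        assert all(v == 0.0 for v in ri.values())


class TestCompareNetworks:
    def test_identical_strata_identical_metrics(self, small_table):
        metrics, contrast, hubs = tn.compare_networks(
            {"a": small_table, "b": small_table}
        )
        assert metrics["a"].edge_density == metrics["b"].edge_density
        assert metrics["a"].modularity == metrics["b"].modularity
        assert hubs["a"] == hubs["b"]

    def test_correlated_stratum_has_higher_density(self):
        members = ["LSS", "LS", "LNSC", "RSS", "RS", "RNSC"]
        mk = lambda rho, seed: tn.generate_dataset(
            tn.SyntheticConfig(
                module_spec={"m": members}, module_loading=rho, species_sd=0.0,
                n_replicates=4, seed=seed,
            )
        )[0]
        metrics, contrast, _ = tn.compare_networks({"hot": mk(0.9, 1), "cold": mk(0.0, 1)})
        assert metrics["hot"].edge_density > metrics["cold"].edge_density

    def test_hub_report_sorted_by_degree_then_label(self, small_table):
        _, m = tn.build_network(small_table)
        hubs = hub_traits(m, top_k=26)
        degrees = [d for _, d in hubs]
        assert degrees == sorted(degrees, reverse=True)
        for (t1, d1), (t2, d2) in zip(hubs, hubs[1:]):
            if d1 == d2:
                assert t1 < t2

    def test_small_stratum_skipped_with_warning(self, small_table):
        tiny = tn.TraitTable(small_table.data.iloc[:2].reset_index(drop=True))
        with pytest.warns(UserWarning, match="skipped"):
            metrics, contrast, _ = tn.compare_networks({"big": small_table, "tiny": tiny})
        assert "tiny" not in metrics

    def test_single_stratum_rejected(self, small_table):
        with pytest.raises(TraitnetError):
            tn.compare_networks({"only": small_table})
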