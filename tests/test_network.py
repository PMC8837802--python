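import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from rhizometa import network as nw


class TestFilterAndCorrelate:
    def test_rare_taxon_removed(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(50, 200, size=(8, 5)),
                              columns=[f"t{j}" for j in range(5)])
        counts["rare"] = 1  # mean relative abundance ~0.1% -> keep at 0.02%
        counts["ultrarare"] = [1, 0, 0, 0, 0, 0, 0, 0]
        rho, p, q = nw.filter_and_correlate(counts, min_relabund=0.0002)
        assert "ultrarare" not in rho.columns
        assert "rare" in rho.columns

    def test_monotone_pair_and_symmetry(self):
        counts = pd.DataFrame({
            "a": [1, 2, 3, 4, 5, 6],
            "b": [10, 20, 30, 40, 50, 60],
            "c": [6, 4, 5, 2, 3, 1],
        })
        rho, p, q = nw.filter_and_correlate(counts, min_relabund=0.0)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T)
        assert np.allclose(np.diag(rho.to_numpy()), 1.0)


class TestRmtThreshold:
    def test_two_perfect_blocks_choose_smallest_candidate(self):
        labels = np.repeat([0, 1], 8)
        rho = pd.DataFrame((labels[:, None] == labels[None, :]).astype(float))
        res = nw.rmt_threshold(rho)
        assert res["threshold"] == pytest.approx(0.30)
        assert res["converged"]

    def test_null_noise_threshold_above_null_tail(self):
        """On pure noise the chosen threshold should exceed the 99th
        percentile of null |rho| in nearly every replicate."""
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=(50, 100))
            rho_m, _ = ss.spearmanr(x)
            res = nw.rmt_threshold(pd.DataFrame(rho_m))
            null99 = np.quantile(np.abs(rho_m[np.triu_indices(100, 1)]), 0.99)
            wins += res["threshold"] > null99
        assert wins >= 16

    def test_planted_blocks_recovered(self):
        """Edges retained at the RMT threshold recover within-block pairs and
        reject cross-block pairs on block-correlated data."""
        for rep in range(10):
            rng = np.random.default_rng(2000 + rep)
            blocks = np.repeat(np.arange(10), 10)
            z = (math.sqrt(0.8) * rng.normal(size=(50, 10))[:, blocks]
                 + math.sqrt(0.2) * rng.normal(size=(50, 100)))
            rho_m, _ = ss.spearmanr(z)
            t = nw.rmt_threshold(pd.DataFrame(rho_m))["threshold"]
            iu = np.triu_indices(100, 1)
            within = blocks[iu[0]] == blocks[iu[1]]
            kept = np.abs(rho_m[iu]) >= t
            assert kept[within].mean() >= 0.90
            assert kept[~within].mean() <= 0.05

    def test_bad_grid_rejected(self):
        rho = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            nw.rmt_threshold(rho, grid=[0.5, 0.4])


class TestBuildNetwork:
    def _matrices(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        r = rng.uniform(-1, 1, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        q = rng.uniform(0, 1, size=(n, n))
        q = np.minimum(q, q.T)
        np.fill_diagonal(q, 0.0)
        taxa = [f"t{j}" for j in range(n)]
        return (pd.DataFrame(r, index=taxa, columns=taxa),
                pd.DataFrame(q, index=taxa, columns=taxa))

    def test_edges_match_bruteforce_pair_scan(self):
        rho, q = self._matrices(n=12, seed=3)
        g = nw.build_network(rho, q, rho_star=0.3, q_threshold=0.5)
        expected = {
            tuple(sorted((rho.index[i], rho.index[j])))
            for i in range(12) for j in range(i + 1, 12)
            if q.iloc[i, j] < 0.5 and abs(rho.iloc[i, j]) >= 0.3
        }
        assert {tuple(sorted(e)) for e in g.edges} == expected

    def test_all_insignificant_is_an_error(self):
        rho, q = self._matrices()
        with pytest.raises(ValueError, match="empty network"):
            nw.build_network(rho, q + 1.0, rho_star=0.1, q_threshold=0.05)

    def test_phylum_labels_joined(self):
        rho, q = self._matrices(n=4, seed=1)
        taxonomy = pd.DataFrame({"Phylum": ["P1", "P2", "P1", "P2"]},
                                index=rho.index)
        g = nw.build_network(rho, q, rho_star=0.0, q_threshold=1.0,
                             taxonomy=taxonomy)
        assert all(g.nodes[n]["phylum"] in {"P1", "P2"} for n in g.nodes)


class TestModularity:
    def test_two_triangles_q_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        res = nw.greedy_modules(g)
        assert res["modularity"] == pytest.approx(0.5, abs=1e-12)
        assert res["n_modules"] == 2

    def test_complete_graph_single_module_q_zero(self):
        g = nx.complete_graph(6)
        q = nx.community.modularity(g, [set(g.nodes)])
        assert q == pytest.approx(0.0, abs=1e-12)
        res = nw.greedy_modules(g)
        assert res["modularity"] >= q - 1e-12

    def test_returned_q_matches_direct_newman_formula(self, small_bundle):
        from rhizometa import pipeline as pl
        counts = small_bundle.counts.iloc[:12]
        rho, p, q = nw.filter_and_correlate(counts, 0.0002)
        g = nw.build_network(rho, q, 0.5, q_threshold=0.2)
        res = nw.greedy_modules(g)
        # direct evaluation: Q = sum_s (e_ss - a_s^2)
        m = g.number_of_edges()
        by_mod = {}
        for node, mod in res["assignment"].items():
            by_mod.setdefault(mod, set()).add(node)
        q_direct = 0.0
        for nodes in by_mod.values():
            e_ss = sum(1 for u, v in g.edges if u in nodes and v in nodes) / m
            a_s = sum(g.degree(n) for n in nodes) / (2 * m)
            q_direct += e_ss - a_s ** 2
        assert res["modularity"] == pytest.approx(q_direct, abs=1e-12)


def _roles_bruteforce(graph, assignment):
    """Independent naive Zi/Pi implementation for the equivalence check."""
    rows = {}
    for node in graph.nodes:
        mod = assignment[node]
        members = [n for n in graph.nodes if assignment[n] == mod]
        within = {m: sum(1 for x in graph.neighbors(m) if assignment[x] == mod)
                  for m in members}
        vals = list(within.values())
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        zi = (within[node] - mean) / sd if sd > 0 else 0.0
        k = graph.degree(node)
        shares = {}
        for nb in graph.neighbors(node):
            shares[assignment[nb]] = shares.get(assignment[nb], 0) + 1
        pi = 1.0 - sum((c / k) ** 2 for c in shares.values())
        if zi > 2.5:
            cat = "network hub" if pi > 0.62 else "module hub"
        else:
            cat = "connector" if pi > 0.62 else "peripheral"
        rows[node] = (zi, pi, cat)
    return rows


class TestNodeRoles:
    def test_all_links_within_module_gives_pi_zero(self):
        g = nx.complete_graph(4)
        roles = nw.node_roles(g, {n: 0 for n in g.nodes})
        assert (roles["Pi"] == 0.0).all()

    def test_four_way_split_gives_pi_three_quarters(self):
        g = nx.star_graph(4)
        assignment = {0: 0, 1: 0, 2: 1, 3: 2, 4: 3}
        roles = nw.node_roles(g, assignment)
        assert roles.loc[0, "Pi"] == pytest.approx(0.75)

    @pytest.mark.parametrize("zi,pi,expected", [
        (2.6, 0.5, "module hub"), (2.6, 0.7, "network hub"),
        (1.0, 0.7, "connector"), (1.0, 0.5, "peripheral"),
    ])
    def test_category_thresholds(self, zi, pi, expected):
        if zi > nw.ZI_THRESHOLD:
            cat = (nw.ROLE_NETWORK_HUB if pi > nw.PI_THRESHOLD
                   else nw.ROLE_MODULE_HUB)
        else:
            cat = (nw.ROLE_CONNECTOR if pi > nw.PI_THRESHOLD
                   else nw.ROLE_PERIPHERAL)
        assert cat == expected

    def test_matches_bruteforce_on_random_graphs(self):
        for seed in range(8):
            g = nx.gnp_random_graph(25, 0.2, seed=seed)
            g.remove_nodes_from([n for n, d in dict(g.degree()).items() if d == 0])
            if g.number_of_nodes() < 4:
                continue
            res = nw.greedy_modules(g)
            roles = nw.node_roles(g, res["assignment"])
            expected = _roles_bruteforce(g, res["assignment"])
            for node, (zi, pi, cat) in expected.items():
                assert roles.loc[node, "Zi"] == pytest.approx(zi, abs=1e-12)
                assert roles.loc[node, "Pi"] == pytest.approx(pi, abs=1e-12)
                assert roles.loc[node, "category"] == cat

    def test_categories_partition_nodes(self, small_bundle):
        counts = small_bundle.counts.iloc[:16]
        rho, p, q = nw.filter_and_correlate(counts, 0.0002)
        g = nw.build_network(rho, q, 0.5, q_threshold=0.2)
        roles = nw.node_roles(g, nw.greedy_modules(g)["assignment"])
        assert len(roles) == g.number_of_nodes()
        assert roles["category"].isin([nw.ROLE_MODULE_HUB, nw.ROLE_NETWORK_HUB,
                                       nw.ROLE_CONNECTOR, nw.ROLE_PERIPHERAL]).all()


class TestNaturalConnectivity:
    def test_single_isolated_node_is_zero(self):
        g = nx.Graph()
        g.add_node("only")
        assert nw.natural_connectivity(g) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_eigenvalue_oracle(self):
        expected = math.log((math.e ** 2 + 2 * math.e ** -1) / 3)
        assert nw.natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-10)

    def test_path_eigenvalue_oracle(self):
        s = math.sqrt(2)
        expected = math.log((math.exp(s) + 1 + math.exp(-s)) / 3)
        assert nw.natural_connectivity(nx.path_graph(3)) == pytest.approx(
            expected, abs=1e-10)

    def test_monotone_under_edge_addition(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(12, 0.2, seed=4)
        base = nw.natural_connectivity(g)
        non_edges = list(nx.non_edges(g))
        u, v = non_edges[rng.integers(len(non_edges))]
        g.add_edge(u, v)
        assert nw.natural_connectivity(g) >= base


class TestRobustnessCurve:
    def test_complete_graph_deterministic_curve(self):
        g = nx.complete_graph(10)
        curve = nw.robustness_curve(g)
        assert len(curve) == int(0.8 * 10) + 1
        assert curve["fraction_removed"].is_monotonic_increasing
        # K_n minus k nodes is K_{n-k}: connectivity depends on count only
        expected = [nw.natural_connectivity(nx.complete_graph(10 - k))
                    for k in range(9)]
        assert np.allclose(curve["natural_connectivity"], expected)

    def test_curve_length_postcondition(self):
        g = nx.gnp_random_graph(23, 0.3, seed=1)
        curve = nw.robustness_curve(g)
        assert len(curve) == int(np.floor(0.8 * 23)) + 1
        assert curve["fraction_removed"].iloc[0] == 0.0
        assert curve["fraction_removed"].iloc[-1] <= 0.8

    def test_denser_graph_curve_dominates(self):
        """With a shared removal order, a graph with 20% extra random edges
        stays a supergraph at every step, so its robustness curve dominates
        pointwise in every paired replicate."""
        reps = 20
        for rep in range(reps):
            g = nx.gnp_random_graph(30, 0.15, seed=rep)
            dense = g.copy()
            rng = np.random.default_rng(rep)
            extra = int(0.2 * g.number_of_edges())
            candidates = list(nx.non_edges(g))
            for idx in rng.choice(len(candidates), size=extra, replace=False):
                dense.add_edge(*candidates[idx])
            base = nw.robustness_curve(g, order="random",
                                       seed=rep)["natural_connectivity"]
            up = nw.robustness_curve(dense, order="random",
                                     seed=rep)["natural_connectivity"]
            assert (up.to_numpy() >= base.to_numpy() - 1e-9).all()

    def test_too_small_graph_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            nw.robustness_curve(nx.path_graph(4))
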