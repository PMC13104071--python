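import networkx as nx
import numpy as np
import pytest
from scipy.linalg import expm

from permacomm.networks import (
    align_samples_by_depth, build_network, core_edge_analytics,
    natural_connectivity, robustness_curve, single_sample_networks,
    sparcc_correlations, sparcc_pvalues, topology,
)
from conftest import lognormal_compositional_counts, make_table


class TestDepthAlignment:
    def test_equal_groups_unchanged(self):
        t = make_table(np.arange(12).reshape(3, 4) + 1)
        out, dd = align_samples_by_depth(
            {"a": t, "b": t}, {"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert out["a"].n_samples == 4
        assert np.array_equal(out["a"].counts, t.counts)

    def test_smallest_gap_merged_first(self):
        # depths 1,2,10,11: the 1-2 pair has the smallest gap -> merged
        counts = np.array([[10, 20, 30, 40], [2, 4, 6, 8]])
        t = make_table(counts)
        small = make_table(counts[:, :3])
        out, dd = align_samples_by_depth(
            {"big": t, "ref": small},
            {"big": [1.0, 2.0, 10.0, 11.0], "ref": [1, 2, 3]})
        assert out["big"].n_samples == 3
        assert np.allclose(dd["big"], [1.5, 10.0, 11.0])
        assert np.array_equal(out["big"].counts[:, 0], [15, 3])

    def test_depth_order_preserved(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(1, 9, (4, 10)))
        out, dd = align_samples_by_depth(
            {"g": t, "r": make_table(rng.integers(1, 9, (4, 5)))},
            {"g": np.linspace(0.5, 9, 10), "r": np.linspace(1, 5, 5)})
        assert (np.diff(dd["g"]) > 0).all()

    def test_tiny_target_rejected(self):
        t = make_table([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            align_samples_by_depth({"a": t}, {"a": [1, 2]})


class TestSparcc:
    def test_planted_correlation_recovered(self):
        counts = lognormal_compositional_counts(rho=0.8, seed=1)
        rho = sparcc_correlations(counts, seed=1)
        assert abs(rho[0, 1] - 0.8) < 0.15

    def test_independent_taxa_near_zero(self):
        counts = lognormal_compositional_counts(rho=0.0, seed=2)
        rho = sparcc_correlations(counts, seed=2)
        off = np.abs(rho)
        np.fill_diagonal(off, 0.0)
        assert off.mean() < 0.1

    def test_sample_order_invariance_exact(self):
        counts = lognormal_compositional_counts(
            n_taxa=15, n_samples=30, seed=3)
        rho1 = sparcc_correlations(counts, seed=5)
        perm = np.random.default_rng(4).permutation(30)
        rho2 = sparcc_correlations(counts[:, perm], seed=5)
        assert np.allclose(rho1, rho2)

    def test_agrees_with_clr_pearson(self):
        # cross-method oracle: basis correlations track the Pearson
        # correlation of clr-transformed counts
        rng = np.random.default_rng(4)
        n = 60
        cov = 0.3 * np.ones((n, n)) + 0.7 * np.eye(n)
        z = rng.normal(0, 1, (150, n)) @ np.linalg.cholesky(cov).T
        x = np.exp(rng.normal(0, 1, n)[None, :] + z)
        frac = x / x.sum(axis=1, keepdims=True)
        counts = np.vstack(
            [rng.multinomial(8000, frac[j]) for j in range(150)]).T
        rho = sparcc_correlations(counts, seed=0)
        logc = np.log(counts + 1.0)
        clr = logc - logc.mean(axis=0, keepdims=True)
        pear = np.corrcoef(clr)
        iu = np.triu_indices(n, 1)
        assert np.abs(rho[iu] - pear[iu]).mean() < 0.1

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            sparcc_correlations(np.ones((3, 20), int))


class TestSparccPvalues:
    def test_strong_pair_saturates(self):
        counts = lognormal_compositional_counts(
            n_taxa=12, n_samples=60, rho=0.95, seed=5, depth=3000)
        rho = sparcc_correlations(counts, seed=5)
        p = sparcc_pvalues(counts, rho, n_boot=19, seed=6)
        assert p[0, 1] == pytest.approx(1 / 20)

    def test_resolution_is_one_over_nboot_plus_one(self):
        counts = lognormal_compositional_counts(
            n_taxa=8, n_samples=20, seed=7, depth=500)
        rho = sparcc_correlations(counts, seed=7)
        p = sparcc_pvalues(counts, rho, n_boot=19, seed=8)
        iu = np.triu_indices(8, 1)
        steps = p[iu] * 20
        assert np.allclose(steps, np.round(steps))

    def test_low_nboot_rejected(self):
        with pytest.raises(ValueError):
            sparcc_pvalues(np.ones((5, 12), int), np.eye(5), n_boot=10)


class TestBuildNetworkAndTopology:
    def _net(self, rho, p, r_min=0.35):
        ids = [f"T{i}" for i in range(rho.shape[0])]
        return build_network(rho, p, ids, r_min=r_min)

    def test_thresholds_respected(self):
        rho = np.array([[1, 0.5, 0.2], [0.5, 1, -0.6], [0.2, -0.6, 1]])
        p = np.full((3, 3), 0.01)
        net = self._net(rho, p)
        assert net.n_edges == 2
        signs = {tuple(sorted(e)): d["sign"]
                 for *e, d in net.graph.edges(data=True)}
        assert signs[("T1", "T2")] == -1

    def test_empty_network_allowed(self):
        rho = np.eye(4)
        net = self._net(rho, np.ones((4, 4)))
        assert net.n_edges == 0
        ts = topology(net)
        assert ts.density == 0.0 and ts.degenerate

    def test_complete_graph_density_one(self):
        rho = np.full((4, 4), 0.9)
        net = self._net(rho, np.full((4, 4), 0.001))
        assert topology(net).density == 1.0

    def test_triangle_hand_values(self):
        rho = np.full((3, 3), 0.9)
        net = self._net(rho, np.full((3, 3), 0.001))
        ts = topology(net)
        assert ts.density == 1.0
        assert ts.transitivity == 1.0
        assert ts.linkage_density == pytest.approx(2.0)
        assert ts.proportion_positive_edges == 1.0

    def test_star_transitivity_zero(self):
        rho = np.eye(4)
        rho[0, 1:] = rho[1:, 0] = 0.9
        net = self._net(rho, np.full((4, 4), 0.001))
        assert topology(net).transitivity == 0.0


class TestNaturalConnectivity:
    def test_edgeless_graph_is_zero(self):
        assert natural_connectivity(np.zeros((7, 7))) == pytest.approx(0.0)

    def test_triangle_closed_form(self):
        expected = np.log((np.e ** 2 + 2 / np.e) / 3)
        assert natural_connectivity(nx.complete_graph(3)) == pytest.approx(
            expected, abs=1e-10)

    def test_larger_clique_more_connected(self):
        assert natural_connectivity(nx.complete_graph(4)) > \
            natural_connectivity(nx.complete_graph(3))

    def test_eigen_equals_matrix_exponential_trace(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 100)
            g = nx.gnp_random_graph(int(n), 0.15, seed=int(rng.integers(1e6)))
            adj = nx.to_numpy_array(g)
            via_eig = natural_connectivity(adj)
            via_expm = np.log(np.trace(expm(adj)) / len(adj))
            assert abs(via_eig - via_expm) <= 1e-8


class TestRobustness:
    def _network(self, n=20, p=0.3, seed=0):
        g = nx.gnp_random_graph(n, p, seed=seed)
        rho = np.eye(n)
        pm = np.ones((n, n))
        for u, v in g.edges:
            rho[u, v] = rho[v, u] = 0.9
            pm[u, v] = pm[v, u] = 0.001
        return build_network(rho, pm, [f"T{i}" for i in range(n)])

    def test_zero_fraction_keeps_nc(self):
        net = self._network()
        rc = robustness_curve(net, fractions=[0.0, 0.5], n_rep=5, seed=1)
        assert rc.nc_mean[0] == pytest.approx(natural_connectivity(net))
        assert rc.nc_normalized[0] == pytest.approx(1.0)

    def test_full_removal_reaches_zero(self):
        net = self._network()
        rc = robustness_curve(net, fractions=[1.0], n_rep=3, seed=1)
        assert rc.nc_mean[0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_nc_non_increasing(self):
        net = self._network(seed=2)
        rc = robustness_curve(net, fractions=np.linspace(0, 1, 6),
                              n_rep=100, seed=3)
        assert (np.diff(rc.nc_mean) <= 1e-9).all()

    def test_edgeless_rejected(self):
        net = build_network(np.eye(4), np.ones((4, 4)),
                            ["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            robustness_curve(net)


class TestSingleSampleNetworks:
    def test_duplicated_sample_gets_equal_scores(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 60, size=(8, 11))
        counts[:, 10] = counts[:, 9]          # duplicate the last sample
        t = make_table(counts)
        out = single_sample_networks(t, t.taxon_ids[:6], r_min=0.3, seed=1)
        s9 = out["_scores"]["S9"]
        s10 = out["_scores"]["S10"]
        assert np.allclose(s9, s10)
        assert out["S9"] == out["S10"]

    def test_homogeneous_samples_have_comparable_counts(self):
        # i.i.d. multinomial draws from one composition: no sample should
        # be an interaction outlier
        rng = np.random.default_rng(9)
        p = rng.dirichlet(np.ones(10) * 5)
        counts = rng.multinomial(2000, p, size=24).T
        t = make_table(counts)
        out = single_sample_networks(t, t.taxon_ids[:8], r_min=0.35, seed=2)
        vals = np.array([out[s] for s in t.sample_ids])
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        assert (np.abs(vals - med) <= 3 * mad).all()

    def test_planted_pair_elevates_its_sample(self):
        # one outlier sample carries an extreme joint excursion of a core
        # pair; its leave-one-out score for that pair dominates
        rng = np.random.default_rng(3)
        counts = rng.integers(5, 40, size=(8, 16))
        counts[0, 0] = counts[1, 0] = 4000
        t = make_table(counts)
        out = single_sample_networks(t, t.taxon_ids, r_min=0.35, seed=4)
        pair_scores = {s: out["_scores"][s][0, 1] for s in t.sample_ids}
        assert pair_scores["S0"] == max(pair_scores.values())

    def test_too_few_samples_rejected(self):
        t = make_table(np.ones((6, 5), int))
        with pytest.raises(ValueError):
            single_sample_networks(t, t.taxon_ids[:3])


class TestCoreEdgeAnalytics:
    def _annotated_net(self, edges, core, phyla=None):
        g = nx.Graph()
        g.add_edges_from(edges)
        for n in g.nodes:
            g.nodes[n]["core"] = n in core
            g.nodes[n]["phylum"] = (phyla or {}).get(n, "P1")
        from permacomm.networks import CorrelationNetwork
        return CorrelationNetwork(graph=g, r_min=0.35, p_max=0.05)

    def test_single_core_core_edge_counted(self):
        net = self._annotated_net([("a", "b"), ("b", "c")], core={"a", "b"})
        out = core_edge_analytics(net)
        assert out.block_counts[("core", "core")] == 1
        assert out.block_counts[("core", "other")] == 1

    def test_core_path_graph_mean_path_length(self):
        net = self._annotated_net([("a", "b"), ("b", "c")],
                                  core={"a", "b", "c"})
        out = core_edge_analytics(net)
        assert out.mean_core_path_length == pytest.approx(4 / 3)

    def test_isolated_core_nodes_flagged(self):
        net = self._annotated_net([("x", "y")], core=set())
        g = net.graph
        g.add_node("c1", core=True, phylum="P1")
        g.add_node("c2", core=True, phylum="P1")
        out = core_edge_analytics(net)
        assert out.empty
        assert out.mean_core_path_length is None


class TestTargetedAttack:
    def test_targeted_removal_is_deterministic(self):
        import networkx as nx
        from permacomm.networks import build_network, robustness_curve
        g = nx.barbell_graph(6, 1)    # a bridge edge with high betweenness
        n = g.number_of_nodes()
        rho = np.eye(n)
        pm = np.ones((n, n))
        for u, v in g.edges:
            rho[u, v] = rho[v, u] = 0.9
            pm[u, v] = pm[v, u] = 0.001
        net = build_network(rho, pm, [f"T{i}" for i in range(n)])
        t1 = robustness_curve(net, fractions=[0.0, 0.2], targeted=True)
        t2 = robustness_curve(net, fractions=[0.0, 0.2], targeted=True)
        assert np.allclose(t1.nc_mean, t2.nc_mean)
        assert t1.nc_mean[1] < t1.nc_mean[0]
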