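"""Network construction, edge statistics, and graph measures."""

import itertools

import networkx as nx
import numpy as np
import pytest

import fusednet as fn
from fusednet.netgraph import (
    BinaryNetwork,
    ThresholdSelectionError,
    network_summary,
)


def _sym(K, rng=None, fill=0.0):
    m = np.full((K, K), fill)
    np.fill_diagonal(m, 0.0)
    return m


def _net_from_graph(g, K=None):
    K = K or g.number_of_nodes()
    return BinaryNetwork(nx.to_numpy_array(g, nodelist=range(K)) > 0)


class TestBinarize:
    def test_threshold_above_max_gives_empty_graph(self, rng):
        v = rng.random((6, 6)) * 0.4
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        assert fn.binarize(v, 0.9).n_edges == 0

    def test_low_threshold_gives_complete_graph(self):
        v = _sym(5, fill=0.5)
        net = fn.binarize(v, 0.01)
        assert net.n_edges == 5 * 4 // 2

    def test_edge_count_matches_bruteforce(self, rng):
        v = rng.random((10, 10))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        thr = 0.5
        net = fn.binarize(v, thr)
        brute = sum(
            1 for i in range(10) for j in range(i + 1, 10) if v[i, j] >= thr
        )
        assert net.n_edges == brute

    @pytest.mark.parametrize("thr", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_out_of_range_rejected(self, thr):
        with pytest.raises(ValueError):
            fn.binarize(_sym(4, fill=0.5), thr)

    def test_density_monotone_in_threshold(self, rng):
        v = rng.random((20, 20))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        dens = [fn.density(fn.binarize(v, t)) for t in (0.8, 0.5, 0.2)]
        assert dens == sorted(dens)
        assert all(0 <= d <= 1 for d in dens)


class TestSelectThreshold:
    def test_engineered_matrix_selects_030(self):
        # a small-world graph whose edge weights all lie in (0.30, 0.31):
        # thresholds <= 0.30 keep the full graph (both criteria pass),
        # 0.31 and above empty it, so the largest satisfying value is 0.30
        K = 68
        g = nx.watts_strogatz_graph(K, 10, 0.1, seed=1)
        w = np.zeros((K, K))
        r = np.random.default_rng(1)
        for i, j in g.edges():
            w[i, j] = w[j, i] = 0.301 + 0.008 * r.random()
        assert fn.select_threshold(w, seed=0) == pytest.approx(0.30)

    def test_degree_criterion_uses_2lnK(self):
        # on an all-equal matrix every candidate fails (sigma undefined or
        # <= 1 on a complete graph); the diagnostics expose the criteria
        v = _sym(68, fill=0.5)
        with pytest.raises(ThresholdSelectionError) as err:
            fn.select_threshold(v, seed=0, n_random=5)
        diag = err.value.diagnostics
        passing = diag[diag.degree_ok]
        assert (passing.mean_degree > 2 * np.log(68)).all()
        assert not passing.small_world_ok.any()


class TestPairedEdgeTTest:
    def test_identical_conditions_nothing_significant(self, rng):
        mats = []
        for _ in range(5):
            v = rng.random((10, 10))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            mats.append(v)
        stats_ = fn.paired_edge_ttest(mats, [m.copy() for m in mats])
        assert not stats_.significant.any()
        assert stats_.zero_variance.all()
        assert np.all(stats_.p == 1.0)

    def test_dof_is_n_minus_one(self, rng):
        a = [rng.random((6, 6)) for _ in range(15)]
        a = [np.triu(m, 1) + np.triu(m, 1).T for m in a]
        b = [rng.random((6, 6)) for _ in range(15)]
        b = [np.triu(m, 1) + np.triu(m, 1).T for m in b]
        assert fn.paired_edge_ttest(a, b).dof == 14

    def test_true_effect_detected(self, rng):
        K = 10
        iu = np.triu_indices(K, k=1)
        a, b = [], []
        for _ in range(12):
            va = rng.standard_normal(len(iu[0])) * 0.05
            vb = va.copy()
            vb[0] += 1.0  # one edge with a large paired difference
            for vals, out in ((va, a), (vb, b)):
                m = np.zeros((K, K))
                m[iu] = vals
                m.T[iu] = vals
                out.append(m)
        stats_ = fn.paired_edge_ttest(a, b)
        assert stats_.significant[0]
        assert stats_.significant.sum() == 1

    def test_too_few_subjects_rejected(self, rng):
        m = _sym(4, fill=0.5)
        with pytest.raises(ValueError):
            fn.paired_edge_ttest([m, m], [m, m])


class TestSignificantNetwork:
    def _stats(self, sig_vec, K):
        E = K * (K - 1) // 2
        return fn.EdgeStats(
            t=np.zeros(E), p=np.ones(E), q_threshold=0.05, dof=4,
            significant=sig_vec, K=K, zero_variance=np.zeros(E, bool),
        )

    def test_all_significant_keeps_graph(self):
        net = fn.binarize(_sym(5, fill=0.5), 0.3)
        stats_ = self._stats(np.ones(10, bool), 5)
        assert np.array_equal(
            fn.significant_network(net, stats_).adjacency, net.adjacency
        )

    def test_none_significant_empties_graph(self):
        net = fn.binarize(_sym(5, fill=0.5), 0.3)
        stats_ = self._stats(np.zeros(10, bool), 5)
        assert fn.significant_network(net, stats_).n_edges == 0

    def test_conjunction_is_elementwise(self, rng):
        K = 8
        v = rng.random((K, K))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        net = fn.binarize(v, 0.5)
        sig = rng.random(K * (K - 1) // 2) > 0.5
        stats_ = self._stats(sig, K)
        out = fn.significant_network(net, stats_)
        assert np.array_equal(
            out.adjacency, net.adjacency & stats_.significant_matrix()
        )


def _brute_force_betweenness(g: nx.Graph) -> np.ndarray:
    """Exhaustive shortest-path enumeration oracle for small graphs."""
    nodes = list(g.nodes)
    B = np.zeros(len(nodes))
    for m, n in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, m, n))
        except nx.NetworkXNoPath:
            continue
        r_mn = len(paths)
        for i in nodes:
            if i in (m, n):
                continue
            r_mn_i = sum(1 for p in paths if i in p[1:-1])
            B[i] += r_mn_i / r_mn
    return B


class TestBetweenness:
    def test_complete_graph_all_zero(self):
        net = _net_from_graph(nx.complete_graph(4))
        assert np.allclose(fn.betweenness(net).betweenness, 0.0)

    def test_path_graph(self):
        net = _net_from_graph(nx.path_graph(3))
        assert list(fn.betweenness(net).betweenness) == [0.0, 1.0, 0.0]

    def test_star_graph_center(self):
        net = _net_from_graph(nx.star_graph(4))  # center + 4 leaves
        b = fn.betweenness(net).betweenness
        assert b[0] == 6.0  # C(4,2) leaf pairs, all through the center
        assert np.allclose(b[1:], 0.0)

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 200:
            n = int(rng.integers(3, 9))
            p = float(rng.uniform(0.2, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            net = _net_from_graph(g)
            assert np.allclose(
                fn.betweenness(net).betweenness, _brute_force_betweenness(g)
            )
            checked += 1

    def test_degree_sum_identity(self, rng):
        v = rng.random((12, 12))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        net = fn.binarize(v, 0.5)
        metrics = fn.betweenness(net)
        assert metrics.degree.sum() == 2 * net.n_edges


class TestDensity:
    def test_complete_and_empty(self):
        assert fn.density(_net_from_graph(nx.complete_graph(6))) == 1.0
        assert fn.density(BinaryNetwork(np.zeros((6, 6), bool))) == 0.0

    def test_printed_formula_value(self):
        # K = 68, M = 300 -> 600 / 4556
        g = nx.gnm_random_graph(68, 300, seed=0)
        net = _net_from_graph(g, K=68)
        assert net.n_edges == 300
        assert fn.density(net) == pytest.approx(600 / 4556)

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            fn.density(BinaryNetwork(np.zeros((1, 1), bool)))


class TestSmallWorldSigma:
    def test_watts_strogatz_is_small_world(self):
        net = _net_from_graph(nx.watts_strogatz_graph(68, 8, 0.1, seed=2))
        assert fn.small_world_sigma(net, seed=1) > 1.0

    def test_random_graph_is_its_own_null(self):
        sigmas = []
        for s in range(20):
            g = nx.gnm_random_graph(68, 272, seed=s)
            sigmas.append(
                fn.small_world_sigma(_net_from_graph(g), n_random=10, seed=1)
            )
        assert 0.8 <= np.mean(sigmas) <= 1.2
        assert min(sigmas) > 0.6 and max(sigmas) < 1.4

    def test_deterministic_given_seed(self):
        net = _net_from_graph(nx.watts_strogatz_graph(40, 6, 0.2, seed=3))
        a = fn.small_world_sigma(net, seed=7)
        b = fn.small_world_sigma(net, seed=7)
        assert a == b

    def test_too_sparse_rejected(self):
        net = _net_from_graph(nx.path_graph(10))
        with pytest.raises(ValueError):
            fn.small_world_sigma(net)

    def test_summary_records_failure_note(self):
        summ = network_summary(BinaryNetwork(np.zeros((6, 6), bool)))
        assert summ.small_world_sigma is None
        assert summ.density == 0.0
        assert summ.sigma_note != ""
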