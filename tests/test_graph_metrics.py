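"""Graph metrics against exhaustive-enumeration oracles and networkx,
thresholding edge-count exactness, null-model invariants, AUC properties."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import netshift as ns
from netshift.errors import (
    ConfigurationError,
    DegenerateThresholdError,
    UndefinedMetricError,
)
from netshift.graph_metrics import PRIMARY_GRID, edge_count

# ---------------------------------------------------------------------------
# independent oracles (pure-python exhaustive enumeration)


def floyd_warshall(A):
    n = len(A)
    d = [[0 if i == j else (1 if A[i][j] else math.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def brute_clustering(A):
    n = len(A)
    c = []
    for i in range(n):
        k = sum(A[i])
        if k < 2:
            c.append(0.0)
            continue
        closed = sum(
            1 for j, h in itertools.combinations(range(n), 2)
            if A[i][j] and A[i][h] and A[j][h]
        )
        c.append(2.0 * closed / (k * (k - 1)))
    return sum(c) / n, c


def brute_path_length(A):
    d = floyd_warshall(A)
    finite = [d[i][j] for i in range(len(A)) for j in range(len(A))
              if i != j and math.isfinite(d[i][j])]
    return sum(finite) / len(finite)


def brute_efficiencies(A):
    n = len(A)
    d = floyd_warshall(A)
    inv = [[1.0 / d[i][j] if i != j and math.isfinite(d[i][j]) else 0.0
            for j in range(n)] for i in range(n)]
    eglob = sum(sum(row) for row in inv) / (n * (n - 1))
    e_nodal = [sum(inv[i]) / (n - 1) for i in range(n)]
    eloc_terms = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i][j]]
        if len(nbrs) < 2:
            eloc_terms.append(0.0)
            continue
        sub = [[A[a][b] for b in nbrs] for a in nbrs]
        ds = floyd_warshall(sub)
        m = len(nbrs)
        vals = [1.0 / ds[a][b] for a in range(m) for b in range(m)
                if a != b and math.isfinite(ds[a][b])]
        eloc_terms.append(sum(vals) / (m * (m - 1)))
    return eglob, e_nodal, sum(eloc_terms) / n


def random_adjacency(rng, n, p=0.45):
    A = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    edges = rng.random(iu.size) < p
    A[iu[edges], ju[edges]] = 1.0
    A[ju[edges], iu[edges]] = 1.0
    return A


def net_from_adj(A, mode="binary", sparsity=0.2):
    return ns.ThresholdedNetwork(np.asarray(A, float), sparsity, mode)


# ---------------------------------------------------------------------------
# thresholding


class TestThresholding:
    def test_edge_count_exact_across_primary_grid(self, z90):
        for s in PRIMARY_GRID.points:
            net = ns.threshold_proportional(z90, float(s), mode="binary")
            assert net.n_edges == edge_count(float(s), 90)
        assert edge_count(0.10, 90) == 400

    def test_binary_and_weighted_share_edge_sets(self, z90):
        b = ns.threshold_proportional(z90, 0.15, mode="binary")
        w = ns.threshold_proportional(z90, 0.15, mode="weighted")
        assert np.array_equal(b.adjacency > 0, w.adjacency > 0)
        kept = w.adjacency[w.adjacency > 0]
        assert np.allclose(kept, np.abs(z90)[w.adjacency > 0])

    def test_retained_entries_are_the_largest_magnitudes(self, z90):
        net = ns.threshold_proportional(z90, 0.10, mode="binary")
        mag = np.abs(z90[np.triu_indices(90, 1)])
        cutoff = np.sort(mag)[::-1][net.n_edges - 1]
        kept = np.abs(z90)[np.triu(net.adjacency, 1) > 0]
        assert kept.min() >= cutoff - 1e-15

    def test_degenerate_thresholds_rejected(self, z90):
        with pytest.raises(DegenerateThresholdError):
            ns.threshold_proportional(z90, 1e-6)
        with pytest.raises(DegenerateThresholdError):
            ns.threshold_proportional(z90, 0.999999)

    def test_tie_break_is_deterministic(self):
        z = np.full((6, 6), 0.5)
        np.fill_diagonal(z, 0.0)
        n1 = ns.threshold_proportional(z, 0.4)
        n2 = ns.threshold_proportional(z, 0.4)
        assert np.array_equal(n1.adjacency, n2.adjacency)
        assert n1.n_edges == edge_count(0.4, 6)


# ---------------------------------------------------------------------------
# binary metric kernels vs oracles


class TestBinaryMetricOracles:
    def test_complete_graph_limits(self):
        A = 1.0 - np.eye(5)
        net = net_from_adj(A)
        assert ns.clustering_coefficient(net)[0] == pytest.approx(1.0)
        assert ns.characteristic_path_length(net)[0] == pytest.approx(1.0)
        assert ns.global_efficiency(net) == pytest.approx(1.0)
        assert np.allclose(ns.nodal_efficiency(net), 1.0)

    def test_star_graph_has_no_triangles(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1.0
        net = net_from_adj(A)
        assert ns.clustering_coefficient(net)[0] == 0.0
        assert ns.degree_centrality(net)[0] == 5.0

    def test_path_graph_lp(self):
        A = np.diag(np.ones(3), 1) + np.diag(np.ones(3), -1)
        lp, excluded = ns.characteristic_path_length(net_from_adj(A))
        assert lp == pytest.approx(5.0 / 3.0)  # (1*6 + 2*4 + 3*2)/12
        assert excluded == 0

    def test_disjoint_triangles_exclude_cross_pairs(self):
        A = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(block, 2):
                A[i, j] = A[j, i] = 1.0
        lp, excluded = ns.characteristic_path_length(net_from_adj(A))
        assert lp == pytest.approx(1.0)
        assert excluded == 18  # 3 * 3 cross pairs, both orders

    def test_handshake_lemma(self, rng):
        A = random_adjacency(rng, 10)
        net = net_from_adj(A)
        assert ns.degree_centrality(net).sum() == 2 * net.n_edges

    def test_all_metrics_match_exhaustive_oracle_on_small_graphs(self, rng):
        """Cp, Lp, Eglob, Eloc, nodal efficiency, degree vs pure-python
        exhaustive enumeration on 100 random graphs of <= 8 nodes."""
        checked_lp = 0
        for _ in range(100):
            n = int(rng.integers(3, 9))
            A = random_adjacency(rng, n, p=float(rng.uniform(0.2, 0.8)))
            net = net_from_adj(A)
            Al = A.astype(int).tolist()
            cp, c_i = ns.clustering_coefficient(net)
            cp_o, c_o = brute_clustering(Al)
            assert cp == pytest.approx(cp_o, abs=1e-10)
            assert np.allclose(c_i, c_o, atol=1e-10)
            eglob, e_nodal, eloc = (
                ns.global_efficiency(net),
                ns.nodal_efficiency(net),
                ns.local_efficiency(net),
            )
            eg_o, en_o, el_o = brute_efficiencies(Al)
            assert eglob == pytest.approx(eg_o, abs=1e-10)
            assert np.allclose(e_nodal, en_o, atol=1e-10)
            assert eloc == pytest.approx(el_o, abs=1e-10)
            assert np.array_equal(ns.degree_centrality(net), np.sum(A, axis=1))
            if net.n_edges > 0:
                assert ns.characteristic_path_length(net)[0] == pytest.approx(
                    brute_path_length(Al), abs=1e-10
                )
                checked_lp += 1
        assert checked_lp > 50

    def test_binary_metrics_match_networkx(self, rng):
        """Independent library cross-check on a mid-sized graph."""
        A = random_adjacency(rng, 30, p=0.2)
        net = net_from_adj(A)
        G = nx.from_numpy_array(A)
        assert ns.clustering_coefficient(net)[0] == pytest.approx(
            np.mean(list(nx.clustering(G).values())), abs=1e-10
        )
        assert ns.global_efficiency(net) == pytest.approx(
            nx.global_efficiency(G), abs=1e-10
        )
        assert ns.local_efficiency(net) == pytest.approx(
            nx.local_efficiency(G), abs=1e-10
        )

    def test_efficiencies_bounded_and_edgeless_node_zero(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        net = net_from_adj(A)
        e = ns.nodal_efficiency(net)
        assert e[3] == 0.0
        assert np.all((e >= 0) & (e <= 1))
        with pytest.raises(UndefinedMetricError):
            ns.characteristic_path_length(net_from_adj(np.zeros((4, 4))))


class TestWeightedMetrics:
    def test_uniform_weights_reduce_to_binary(self, rng):
        A = random_adjacency(rng, 12, p=0.4)
        b = net_from_adj(A, "binary")
        w = net_from_adj(A * 0.7, "weighted")
        assert ns.clustering_coefficient(w)[0] == pytest.approx(
            ns.clustering_coefficient(b)[0], abs=1e-12
        )
        assert ns.global_efficiency(w) == pytest.approx(ns.global_efficiency(b), abs=1e-12)
        assert np.allclose(ns.degree_centrality(w), ns.degree_centrality(b))

    def test_strengths_match_hand_sums(self):
        W = np.array(
            [[0.0, 0.2, 0.4], [0.2, 0.0, 0.0], [0.4, 0.0, 0.0]]
        )
        net = net_from_adj(W, "weighted")
        # normalized by max weight 0.4 -> rows sum to (0.5+1.0, 0.5, 1.0)
        assert np.allclose(ns.degree_centrality(net), [1.5, 0.5, 1.0])

    def test_onnela_clustering_matches_networkx(self, rng):
        A = random_adjacency(rng, 10, p=0.5)
        W = A * rng.uniform(0.2, 1.0, size=A.shape)
        W = (W + W.T) / 2
        net = net_from_adj(W, "weighted")
        G = nx.from_numpy_array(W)
        expected = np.mean(list(nx.clustering(G, weight="weight").values()))
        assert ns.clustering_coefficient(net)[0] == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# null models and small-world


class TestNullEnsemble:
    def test_degree_sequence_preserved_and_deterministic(self, z90):
        net = ns.threshold_proportional(z90, 0.10)
        nulls, failed = ns.random_null_ensemble(net, 5, seed=3)
        k0 = ns.degree_centrality(net)
        for m, bad in zip(nulls, failed):
            assert not bad
            assert np.array_equal(ns.degree_centrality(m), k0)
            assert np.allclose(m.adjacency, m.adjacency.T)
            assert np.all(np.diag(m.adjacency) == 0)
        again, _ = ns.random_null_ensemble(net, 5, seed=3)
        assert all(np.array_equal(a.adjacency, b.adjacency) for a, b in zip(nulls, again))
        # rewiring actually moves edges
        assert any(not np.array_equal(m.adjacency, net.adjacency) for m in nulls)

    def test_star_graph_flags_rewiring_failure(self):
        A = np.zeros((6, 6))
        A[0, 1:] = A[1:, 0] = 1.0
        nulls, failed = ns.random_null_ensemble(net_from_adj(A), 3, seed=0)
        assert all(failed)

    def test_self_null_gives_unit_indices(self, z90):
        net = ns.threshold_proportional(z90, 0.12)
        gamma, lam, sigma = ns.small_world(net, [net])
        assert gamma == pytest.approx(1.0) and lam == pytest.approx(1.0)
        assert sigma == pytest.approx(1.0)

    def test_er_graph_is_its_own_null(self, rng):
        # dense enough (~940 expected triangles) that single-draw triangle
        # noise sits well inside the band
        G = nx.gnm_random_graph(90, 801, seed=4)
        A = nx.to_numpy_array(G)
        net = net_from_adj(A)
        nulls, failed = ns.random_null_ensemble(net, 30, seed=5)
        gamma, lam, sigma = ns.small_world(net, nulls, failed)
        assert 0.9 < gamma < 1.1
        assert 0.9 < lam < 1.1

    def test_watts_strogatz_is_small_world(self):
        G = nx.watts_strogatz_graph(90, 8, 0.1, seed=6)
        net = net_from_adj(nx.to_numpy_array(G))
        nulls, failed = ns.random_null_ensemble(net, 20, seed=7)
        gamma, lam, sigma = ns.small_world(net, nulls, failed)
        assert gamma > 1.5
        assert lam < 1.3
        assert sigma > 1.3
        assert sigma == pytest.approx(gamma / lam, abs=1e-12)


class TestHierarchy:
    def test_flat_relation_gives_zero_exponent(self):
        # two disjoint triangles plus a square-with-diagonal: varying k, equal c?
        # simpler: construct exact power law c = k^0 via complete graphs is flat
        G = nx.complete_graph(4)
        H = nx.complete_graph(5)
        A = nx.to_numpy_array(nx.disjoint_union(G, H))
        b = ns.hierarchy(net_from_adj(A))
        assert b == pytest.approx(0.0, abs=1e-10)  # all c_i = 1 across k = 3, 4

    def test_exact_power_law_recovered(self, monkeypatch):
        # synthesize c_i = k_i^-1 exactly by patching the clustering kernel
        k = np.array([2.0, 3.0, 4.0, 5.0, 8.0])
        c = 1.0 / k
        net = net_from_adj(np.zeros((5, 5)))
        monkeypatch.setattr(
            ns.graph_metrics, "clustering_coefficient", lambda _net: (c.mean(), c)
        )
        monkeypatch.setattr(
            ns.ThresholdedNetwork, "pattern",
            lambda self: np.diag(k) @ np.ones((5, 5)) / 5,  # rows sum to k
        )
        assert ns.graph_metrics.hierarchy(net) == pytest.approx(1.0, abs=1e-10)

    def test_regular_graph_degenerate_regressor(self):
        A = nx.to_numpy_array(nx.cycle_graph(6))
        with pytest.raises(UndefinedMetricError):
            ns.hierarchy(net_from_adj(A))


# ---------------------------------------------------------------------------
# AUC and the per-subject sweep


class TestAUC:
    def test_constant_and_linear_closed_forms(self):
        pts = PRIMARY_GRID.points
        assert ns.metric_auc(np.full(13, 3.0), pts) == pytest.approx(0.12 * 3.0)
        lin = np.linspace(2.0, 5.0, 13)
        assert ns.metric_auc(lin, pts) == pytest.approx(0.12 * (2.0 + 5.0) / 2.0)

    def test_grid_point_counts(self):
        assert len(PRIMARY_GRID.points) == 13
        assert len(ns.EXTENDED_GRID.points) == 21

    @given(
        st.lists(st.floats(-10, 10), min_size=13, max_size=13),
        st.lists(st.floats(-10, 10), min_size=13, max_size=13),
        st.floats(-3, 3), st.floats(-3, 3),
    )
    def test_linearity(self, u, v, a, b):
        pts = PRIMARY_GRID.points
        u, v = np.array(u), np.array(v)
        lhs = ns.metric_auc(a * u + b * v, pts)
        rhs = a * ns.metric_auc(u, pts) + b * ns.metric_auc(v, pts)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_non_finite_curve_rejected(self):
        vals = np.full(13, 1.0)
        vals[4] = np.nan
        with pytest.raises(UndefinedMetricError):
            ns.metric_auc(vals, PRIMARY_GRID.points)


@pytest.fixture(scope="module")
def sweep(z90):
    return ns.compute_subject_metrics(z90, n_rand=5, seed=11)


class TestSubjectSweep:
    def test_full_metric_complement(self, sweep):
        assert set(sweep.global_curves) == set(ns.graph_metrics.GLOBAL_METRICS)
        assert set(sweep.nodal_curves) == set(ns.graph_metrics.NODAL_METRICS)
        assert sweep.nodal_curves["degree"].values.shape == (90, 13)
        assert np.asarray(sweep.nodal_auc("degree")).shape == (90,)

    def test_sigma_identity_and_efficiency_bounds(self, sweep):
        g = sweep.global_curves
        assert np.allclose(
            g["sigma"].values, g["gamma"].values / g["lambda"].values, atol=1e-12
        )
        ne = sweep.nodal_curves["nodal_efficiency"].values
        assert np.all((ne >= 0) & (ne <= 1))

    def test_eglob_monotone_in_sparsity(self, sweep):
        eg = sweep.global_curves["Eglob"].values
        assert np.all(np.diff(eg) >= -1e-12)

    def test_deterministic_given_seed(self, z90):
        a = ns.compute_subject_metrics(z90, n_rand=3, seed=2)
        b = ns.compute_subject_metrics(z90, n_rand=3, seed=2)
        assert np.array_equal(
            a.global_curves["gamma"].values, b.global_curves["gamma"].values
        )

    def test_null_metrics_require_ensemble(self, z90):
        with pytest.raises(ConfigurationError):
            ns.compute_subject_metrics(z90, n_rand=0, seed=0)
        sm = ns.compute_subject_metrics(
            z90, n_rand=0, seed=0, global_metrics=("Cp", "Eglob")
        )
        assert set(sm.global_curves) == {"Cp", "Eglob"}
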