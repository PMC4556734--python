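"""Graph measures against brute-force oracles; null models; NDI; hubs."""

import itertools

import numpy as np
import pytest

from endonet import (
    CohortDesign,
    clustering_coefficient,
    correlation_matrix,
    generate_cohort,
    generate_parcellation,
    global_efficiency,
    group_template,
    identify_hubs,
    network_block_weights,
    node_disruption_index,
    node_strengths,
    normalize_metric,
    null_ensemble,
    proportional_threshold,
)
from endonet.connectivity import WeightedNetwork
from endonet.metrics import hub_profile


def net_from(weights):
    w = np.asarray(weights, dtype=float)
    return WeightedNetwork(w, density=1.0, retained_count=int((w != 0).sum() // 2))


def brute_clustering(w):
    """Onnela clustering by explicit triple enumeration."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    w_hat = w / w.max() if w.max() > 0 else w
    coeffs = []
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            coeffs.append(0.0)
            continue
        total = 0.0
        for j, h in itertools.permutations(range(n), 2):
            if j == i or h == i:
                continue
            total += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1 / 3)
        coeffs.append(total / (k * (k - 1)))
    return float(np.mean(coeffs))


def brute_efficiency(w):
    """Efficiency via exhaustive enumeration of simple paths."""
    w = np.asarray(w, dtype=float)
    n = len(w)
    if n < 2:
        return 0.0
    total = 0.0
    nodes = list(range(n))
    for i, j in itertools.permutations(nodes, 2):
        best = np.inf
        others = [k for k in nodes if k not in (i, j)]
        for size in range(len(others) + 1):
            for mids in itertools.permutations(others, size):
                path = [i, *mids, j]
                length = 0.0
                ok = True
                for a, b in zip(path[:-1], path[1:]):
                    if w[a, b] <= 0:
                        ok = False
                        break
                    length += 1.0 / w[a, b]
                if ok:
                    best = min(best, length)
        if np.isfinite(best):
            total += 1.0 / best
    return total / (n * (n - 1))


def random_small_graph(rng):
    n = int(rng.integers(3, 7))
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    mask = rng.random(iu[0].size) < 0.6
    vals = rng.uniform(0.1, 1.0, iu[0].size) * mask
    w[iu] = vals
    w += w.T
    return w


class TestClustering:
    def test_unit_triangle_is_one_and_path_is_zero(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        assert clustering_coefficient(net_from(tri)) == pytest.approx(1.0)
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert clustering_coefficient(net_from(path)) == pytest.approx(0.0)

    def test_triangle_with_pendant_matches_enumeration(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[2, 3] = w[3, 2] = 0.8
        assert clustering_coefficient(net_from(w)) == pytest.approx(brute_clustering(w), abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(60):
            w = random_small_graph(rng)
            assert clustering_coefficient(net_from(w)) == pytest.approx(
                brute_clustering(w), abs=1e-10
            )

    def test_agrees_with_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        w = random_small_graph(rng)
        g = nx.from_numpy_array(w)
        assert clustering_coefficient(net_from(w)) == pytest.approx(
            nx.average_clustering(g, weight="weight"), abs=1e-10
        )

    def test_negative_weights_rejected(self):
        w = np.array([[0, -1.0], [-1.0, 0]])
        with pytest.raises(ValueError, match="threshold"):
            clustering_coefficient(net_from(w))


class TestEfficiency:
    def test_complete_unit_graph(self):
        w = 1.0 - np.eye(5)
        assert global_efficiency(net_from(w)) == pytest.approx(1.0)

    def test_disconnected_dyads(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        assert global_efficiency(net_from(w)) == pytest.approx(1 / 3)

    def test_weighted_three_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.5
        assert global_efficiency(net_from(w)) == pytest.approx(brute_efficiency(w), abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(60):
            w = random_small_graph(rng)
            assert global_efficiency(net_from(w)) == pytest.approx(
                brute_efficiency(w), abs=1e-10
            )


class TestNullEnsemble:
    def test_triangle_nulls_are_weight_permutations(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.2
        net = net_from(w)
        for null in null_ensemble(net, n=5, seed=0):
            iu = np.triu_indices(3, 1)
            assert sorted(null.weights[iu].tolist()) == sorted(w[iu].tolist())
            assert ((null.weights > 0) == (np.ones((3, 3)) - np.eye(3)).astype(bool)).all()

    def test_exact_invariants_on_random_graph(self, rng):
        w = np.zeros((30, 30))
        iu = np.triu_indices(30, 1)
        mask = rng.random(iu[0].size) < 0.25
        w[iu] = rng.uniform(0.1, 1.0, iu[0].size) * mask
        w += w.T
        net = net_from(w)
        degrees = (w > 0).sum(axis=1)
        for null in null_ensemble(net, n=10, seed=3):
            assert null.weights.shape == w.shape
            assert np.allclose(null.weights, null.weights.T)
            assert ((null.weights > 0).sum(axis=1) == degrees).all()
            assert np.allclose(
                np.sort(null.weights[iu][null.weights[iu] != 0]),
                np.sort(w[iu][w[iu] != 0]),
            )

    def test_deterministic_per_seed(self, rng):
        w = random_small_graph(rng)
        net = net_from(w)
        a = null_ensemble(net, n=3, seed=7)
        b = null_ensemble(net, n=3, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)

    def test_validation(self):
        tri = net_from(1.0 - np.eye(3))
        with pytest.raises(ValueError):
            null_ensemble(tri, n=0, seed=0)


class TestNormalizeMetric:
    def test_constant_metric_gives_one(self, rng):
        net = net_from(random_small_graph(rng))
        res = normalize_metric(lambda g: 2.5, net, [net, net])
        assert res.normalized == pytest.approx(1.0)

    def test_self_ensemble_gives_one(self, rng):
        w = random_small_graph(rng)
        net = net_from(w)
        res = normalize_metric(clustering_coefficient, net, [net])
        assert res.normalized == pytest.approx(1.0)

    def test_ring_lattice_clusters_above_null(self):
        n = 30
        w = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                j = (i + d) % n
                w[i, j] = w[j, i] = 1.0
        net = net_from(w)
        res = normalize_metric(clustering_coefficient, net, null_ensemble(net, 20, seed=1))
        assert res.normalized > 1.0


class TestNDI:
    def test_identity_and_scaling(self, rng):
        s = rng.uniform(1, 10, 50)
        assert node_disruption_index(s, s).slope == pytest.approx(0.0, abs=1e-12)
        for k in (0.5, 0.8, 1.2):
            res = node_disruption_index(k * s, s)
            assert res.slope == pytest.approx(k - 1, abs=1e-10)

    def test_constant_offset(self, rng):
        s = rng.uniform(1, 10, 50)
        res = node_disruption_index(s + 3.0, s)
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert res.intercept == pytest.approx(3.0, abs=1e-10)

    def test_degenerate_template_rejected(self):
        with pytest.raises(ValueError):
            node_disruption_index(np.arange(5.0), np.ones(5))

    def test_group_template_and_leave_one_out(self):
        s = np.array([1.0, 2.0, 3.0])
        assert np.allclose(group_template([s, 3 * s]), 2 * s)
        subs = [s, 2 * s, 3 * s]
        assert np.allclose(group_template(subs, leave_one_out=0), 2.5 * s)
        with pytest.raises(ValueError):
            group_template([s])

    def test_gradient_cohorts_order_group_mean_ndi(self):
        # hypoconnectivity gradient: 0 > mean NDI(SIB) > mean NDI(ASC)
        parc = generate_parcellation(60, 6, seed=2)
        by_group = {"CON": [], "SIB": [], "ASC": []}
        for seed in range(20):
            subs = generate_cohort(
                parc, CohortDesign(n_per_group=6, n_timepoints=200, seed=seed)
            )
            strengths = {
                s.subject_id: (
                    s.group,
                    node_strengths(
                        proportional_threshold(correlation_matrix(s.timeseries), 0.2)
                    ),
                )
                for s in subs
            }
            template = group_template(
                [v for g, v in strengths.values() if g == "CON"]
            )
            for g, v in strengths.values():
                by_group[g].append(node_disruption_index(v, template).slope)
        means = {g: np.mean(v) for g, v in by_group.items()}
        assert means["ASC"] < means["SIB"] < 0.0
        assert abs(means["CON"]) < abs(means["SIB"])


class TestHubs:
    def test_top_fraction_by_strength(self):
        parc = generate_parcellation(10, 2, seed=1)
        strengths = np.arange(10.0)
        profile = identify_hubs(strengths, parc, 0.2)
        assert set(profile.hub_indices.tolist()) == {8, 9}

    def test_hub_count_rounding(self):
        parc = generate_parcellation(258, 14, seed=1)
        profile = identify_hubs(np.random.default_rng(0).random(258), parc, 0.2)
        assert profile.hub_indices.size == 52  # round(0.2 * 258)

    def test_hub_fraction_bound(self, rng):
        for n in (10, 37, 101):
            parc = generate_parcellation(n, 3, seed=n)
            profile = identify_hubs(rng.random(n), parc, 0.2)
            assert 0.2 - 1 / n <= profile.hub_indices.size / n <= 0.2 + 1 / n

    def test_counts_cover_analyzed_networks_only(self):
        parc = generate_parcellation(20, 14, seed=4)
        strengths = np.zeros(20)
        # make every node of one analyzed network a hub
        target = parc.networks[0]
        strengths[parc.network_indices(target)] = 10.0
        profile = identify_hubs(strengths, parc, 0.2)
        assert profile.counts[target] >= 1
        assert sum(profile.counts.values()) <= profile.hub_indices.size

    def test_degree_based_alternative(self, rng):
        parc = generate_parcellation(12, 3, seed=5)
        w = random_small_graph(rng)
        # pad to 12 nodes
        full = np.zeros((12, 12))
        full[: w.shape[0], : w.shape[0]] = w
        net = net_from(full)
        prof = hub_profile(net, parc, 0.25, method="degree")
        assert prof.hub_indices.size == 3


class TestNetworkBlocks:
    def test_block_diagonal_has_zero_inter(self):
        parc = generate_parcellation(8, 2, seed=3)
        w = np.zeros((8, 8))
        for network in parc.networks:
            idx = parc.network_indices(network)
            for i, j in itertools.combinations(idx, 2):
                w[i, j] = w[j, i] = 0.5
        blocks = network_block_weights(net_from(w), parc)
        assert np.allclose(blocks["inter"], 0.0)
        assert np.allclose(blocks["intra"], 0.5)

    def test_uniform_weights(self):
        parc = generate_parcellation(9, 3, seed=6)
        w = 0.3 * (1 - np.eye(9))
        blocks = network_block_weights(net_from(w), parc)
        assert np.allclose(blocks["intra"], 0.3)
        assert np.allclose(blocks["inter"], 0.3)

    def test_single_cross_edge(self):
        parc = generate_parcellation(4, 2, seed=7)
        nets = parc.networks
        a = parc.network_indices(nets[0])
        b = parc.network_indices(nets[1])
        w = np.zeros((4, 4))
        w[a[0], b[0]] = w[b[0], a[0]] = 0.6
        blocks = network_block_weights(net_from(w), parc)
        assert blocks.loc[nets[0], "inter"] == pytest.approx(0.6 / 4)
        assert blocks.loc[nets[0], "intra"] == pytest.approx(0.0)


def test_node_strengths_examples():
    tri = 1.0 - np.eye(3)
    assert np.allclose(node_strengths(net_from(tri)), 2.0)
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 0.5
    assert np.allclose(node_strengths(net_from(star)), [1.5, 0.5, 0.5, 0.5])
    assert np.allclose(node_strengths(net_from(np.zeros((3, 3)))), 0.0)
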