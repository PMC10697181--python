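"""Graph measures against brute-force oracles, closed forms and symmetry."""

import numpy as np
import pytest

from conftest import random_weighted_net
from oracles import (
    betweenness_bruteforce,
    betweenness_path_enumeration,
    char_path_length_bruteforce,
    onnela_clustering_bruteforce,
    rich_club_bruteforce,
)
from wconn.core import WeightedConnectome
from wconn.nulls import AnnealParams, NullEnsemble, generate_null_ensemble
from wconn.topology import (
    betweenness_closeness,
    centrality_panel,
    char_path_length,
    hubness_distance,
    hubness_scores,
    normalize_rich_club,
    rich_club_binary,
    rich_club_weighted,
    small_worldness,
    weight_to_length,
    weighted_clustering,
)


def net_from(m, name="COMMIT"):
    return WeightedConnectome(name, "t", np.asarray(m, float))


class TestClustering:
    def test_unit_triangle(self):
        m = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
        np.testing.assert_allclose(weighted_clustering(net_from(m)), 1.0)

    def test_path_graph_zero(self):
        m = np.zeros((4, 4))
        for i in range(3):
            m[i, i + 1] = m[i + 1, i] = 1.0
        np.testing.assert_allclose(weighted_clustering(net_from(m)), 0.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(30):
            net = random_weighted_net(rng, n=12, density=0.5, connected=False)
            np.testing.assert_allclose(
                weighted_clustering(net),
                onnela_clustering_bruteforce(net.matrix),
                atol=1e-12,
            )

    def test_binary_reduction(self):
        # equal weights: weighted clustering equals the binary triangle fraction
        rng = np.random.default_rng(1)
        net = random_weighted_net(rng, n=10, density=0.5, connected=False)
        binary = (net.matrix != 0).astype(float)
        np.testing.assert_allclose(
            weighted_clustering(net_from(binary * 3.7)),
            onnela_clustering_bruteforce(binary),
            atol=1e-12,
        )


class TestPathLength:
    def test_max_weight_edge_zero_length(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 0], [2.0, 0, 0]])
        lengths = weight_to_length(net_from(m))
        assert lengths[0, 2] == 0.0  # the max-weight edge
        assert lengths[0, 1] == pytest.approx(np.log(2))

    def test_two_node_half_max_is_ln2(self):
        # weights already on the (0, 1] scale: L = -ln(0.5) = ln 2
        two = np.array([[0, 0.5], [0.5, 0]])
        L, _ = char_path_length(net_from(two), normalize=False)
        assert L == pytest.approx(np.log(2), rel=1e-12)

    def test_three_node_closed_form(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 0], [2.0, 0, 0]])
        three, _ = char_path_length(net_from(m))
        assert three == pytest.approx((0 + np.log(2) + np.log(2)) * 2 / 6, rel=1e-12)

    def test_uniform_weights_fall_back_to_hop_count(self):
        m = np.ones((3, 3)) - np.eye(3)
        lengths = weight_to_length(net_from(m))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(lengths[off], 1.0)

    def test_matches_floyd_warshall_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(30):
            net = random_weighted_net(rng, n=10, density=0.5)
            L, _ = char_path_length(net)
            assert L == pytest.approx(
                char_path_length_bruteforce(weight_to_length(net)), abs=1e-10
            )

    def test_fully_disconnected_error(self):
        m = np.zeros((3, 3))
        with pytest.raises(Exception):
            char_path_length(net_from(m))


class TestBetweenness:
    def _lengths(self, rng, n, density=0.5):
        net = random_weighted_net(rng, n=n, density=density)
        lengths = np.full((n, n), np.inf)
        nz = net.matrix > 0
        lengths[nz] = rng.uniform(0.2, 3.0, size=int(nz.sum()))
        lengths = np.minimum(lengths, lengths.T)
        np.fill_diagonal(lengths, np.inf)
        return lengths

    def test_star_closed_form(self):
        m = np.zeros((5, 5))
        m[0, 1:] = m[1:, 0] = 1.0
        panel = centrality_panel(net_from(m))
        assert panel.betweenness[0] == pytest.approx((5 - 1) * (5 - 2) / 2)
        np.testing.assert_allclose(panel.betweenness[1:], 0.0)

    def test_uniform_ring_symmetry(self):
        n = 8
        m = np.zeros((n, n))
        for i in range(n):
            m[i, (i + 1) % n] = m[(i + 1) % n, i] = 1.0
        panel = centrality_panel(net_from(m))
        for vals in (panel.strength, panel.betweenness, panel.closeness,
                     panel.eigenvector, panel.clustering):
            np.testing.assert_allclose(vals, vals[0], atol=1e-8)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            lengths = self._lengths(rng, n=10)
            btw, _ = betweenness_closeness(lengths)
            np.testing.assert_allclose(btw, betweenness_bruteforce(lengths), atol=1e-8)

    def test_matches_path_enumeration_small(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            lengths = self._lengths(rng, n=7, density=0.45)
            btw, _ = betweenness_closeness(lengths)
            np.testing.assert_allclose(
                btw, betweenness_path_enumeration(lengths), atol=1e-8
            )


class TestSmallWorld:
    def test_degenerate_nulls_give_unity(self, cohort):
        net = cohort.group["COMMIT"]
        copies = NullEnsemble("weighted-degree-strength", [net] * 5, seed=0)
        rep = small_worldness(net, nulls=copies)
        assert rep.S == pytest.approx(1.0, abs=1e-12)
        assert rep.C == pytest.approx(1.0) and rep.L == pytest.approx(1.0)

    def test_watts_strogatz_regime(self):
        # ring lattice with light rewiring: high clustering, short paths
        rng = np.random.default_rng(5)
        n, k = 100, 4
        m = np.zeros((n, n))
        for i in range(n):
            for off in range(1, k // 2 + 1):
                j = (i + off) % n
                m[i, j] = m[j, i] = 1.0
        # rewire ~2% of edges to random targets
        iu, ju = np.where(np.triu(m, 1))
        for e in rng.choice(len(iu), size=4, replace=False):
            i = iu[e]
            choices = np.flatnonzero(m[i] == 0)
            choices = choices[choices != i]
            j_new = int(rng.choice(choices))
            m[i, ju[e]] = m[ju[e], i] = 0.0
            m[i, j_new] = m[j_new, i] = 1.0
        net = net_from(m + m.T * 0)  # already symmetric
        fast = AnnealParams(cooling=0.9, patience=10, max_sweeps=200)
        rep = small_worldness(net, n_nulls=10, seed=6, swaps_per_edge=10)
        assert rep.S > 1.0

    def test_dense_random_graph_near_unity(self):
        rng = np.random.default_rng(7)
        vals = []
        fast = AnnealParams(cooling=0.9, patience=10, max_sweeps=300)
        for seed in range(5):
            net = random_weighted_net(rng, n=40, density=0.6)
            ens = generate_null_ensemble(net, n_nulls=8, swaps_per_edge=10,
                                         anneal=fast, seed=seed)
            vals.append(small_worldness(net, nulls=ens).S)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)


class TestHubness:
    def test_star_center_scores_high(self):
        m = np.zeros((5, 5))
        m[0, 1:] = m[1:, 0] = 1.0
        table = hubness_scores(centrality_panel(net_from(m)))
        assert table.score[0] >= 4

    def test_ring_tie_rule_deterministic(self):
        n = 10
        m = np.zeros((n, n))
        for i in range(n):
            m[i, (i + 1) % n] = m[(i + 1) % n, i] = 1.0
        table = hubness_scores(centrality_panel(net_from(m)))
        # perfectly symmetric: index tie-break gives each point to the
        # first ceil(0.2 n) = 2 nodes
        assert (table.score[:2] == 5).all()
        assert (table.score[2:] == 0).all()

    def test_scores_bounded(self):
        rng = np.random.default_rng(8)
        for trial in range(50):
            net = random_weighted_net(rng, n=8, density=0.6)
            table = hubness_scores(centrality_panel(net))
            assert table.score.min() >= 0 and table.score.max() <= 5

    def test_distance_hand_example(self):
        def fake(scores):
            z = np.zeros(4)
            return type("T", (), {"score": np.array(scores), "n_nodes": 4,
                                  "strength": z, "betweenness": z, "closeness": z,
                                  "eigenvector": z, "clustering": z})()
        names, d = hubness_distance({"a": fake([3, 2, 0, 5]), "b": fake([1, 2, 4, 0])})
        assert d[0, 1] == pytest.approx(np.sqrt(4 + 0 + 16 + 25))
        assert d[0, 0] == 0 and d[1, 0] == d[0, 1]

    def test_identical_tables_zero_distance(self, cohort):
        t = hubness_scores(centrality_panel(cohort.group["COMMIT"]))
        _, d = hubness_distance({"a": t, "b": t})
        assert d[0, 1] == 0.0


class TestRichClub:
    def test_uniform_complete_graph_phi_one(self):
        n = 6
        m = np.ones((n, n)) - np.eye(n)
        curve = rich_club_weighted(net_from(m))
        ok = np.isfinite(curve.phi)
        np.testing.assert_allclose(curve.phi[ok], 1.0)

    def test_k4_minus_edge_binary(self):
        m = np.ones((4, 4)) - np.eye(4)
        m[0, 1] = m[1, 0] = 0.0  # degrees {2, 2, 3, 3}
        curve = rich_club_binary(net_from(m))
        assert curve.phi[curve.k == 1][0] == pytest.approx(5 / 6)

    def test_matches_per_k_oracle(self):
        rng = np.random.default_rng(9)
        for trial in range(15):
            net = random_weighted_net(rng, n=15, density=0.4, connected=False)
            for weighted, fn in ((True, rich_club_weighted), (False, rich_club_binary)):
                curve = fn(net)
                for t, k in enumerate(curve.k):
                    expected = rich_club_bruteforce(net.matrix, int(k), weighted)
                    if np.isnan(expected):
                        assert np.isnan(curve.phi[t])
                    else:
                        assert curve.phi[t] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_nulls_give_unity_no_detection(self, cohort):
        net = cohort.group["COMMIT"]
        copies = NullEnsemble("weighted-degree-strength", [net] * 5, seed=0)
        curve = normalize_rich_club(rich_club_weighted(net), copies)
        ok = np.isfinite(curve.phi_norm)
        np.testing.assert_allclose(curve.phi_norm[ok], 1.0)
        assert curve.detected == []


class TestEquivariance:
    def test_measures_commute_with_relabeling(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            net = random_weighted_net(rng, n=9, density=0.5)
            perm = rng.permutation(9)
            pm = net.matrix[np.ix_(perm, perm)]
            pnet = net_from(pm)
            np.testing.assert_allclose(
                weighted_clustering(pnet), weighted_clustering(net)[perm], atol=1e-12
            )
            a, _ = char_path_length(net)
            b, _ = char_path_length(pnet)
            assert a == pytest.approx(b, abs=1e-12)
            ca, cb = curve_pair = rich_club_weighted(net), rich_club_weighted(pnet)
            np.testing.assert_allclose(ca.phi, cb.phi, atol=1e-12, equal_nan=True)
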