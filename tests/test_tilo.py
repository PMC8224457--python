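import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from tilokit import synthio, tilo
from tilokit.tilo import (
    TADNetwork,
    arrangement_cost,
    build_tad_network,
    cut_profile,
    oracle_best_ordering,
    order_nodes,
    pinch_ratios,
    slice_network,
    tilo_cluster,
)


def random_w(n, rng):
    w = rng.random((n, n))
    w = w + w.T
    np.fill_diagonal(w, 0.0)
    return w


def chain_network(weights):
    """Path graph a-b-c-... with the given consecutive edge weights."""
    n = len(weights) + 1
    w = np.zeros((n, n))
    for k, x in enumerate(weights):
        w[k, k + 1] = w[k + 1, k] = x
    return w


class TestBuildNetwork:
    def test_two_tads_constant_oe(self):
        from tilokit.hicio import BinnedContactMap, GenomicInterval

        cmap = BinnedContactMap("chr1", 1000, np.full((8, 8), 3.0))
        tads = [GenomicInterval("chr1", 0, 4000), GenomicInterval("chr1", 4000, 8000)]
        net = build_tad_network(cmap, tads)
        assert net.n == 2
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 0] == 0.0

    def test_planted_cluster_edge_contrast(self, study_sim):
        cmap, truth = study_sim
        net = build_tad_network(cmap, truth.tads)
        labels = truth.cluster_labels
        same = np.equal.outer(labels, labels) & ~np.eye(net.n, dtype=bool)
        diff = ~np.equal.outer(labels, labels)
        ratio = net.weights[same].mean() / net.weights[diff].mean()
        assert ratio == pytest.approx(truth.params.cluster_fold, rel=0.10)

    def test_symmetry_zero_diagonal(self, study_sim):
        cmap, truth = study_sim
        net = build_tad_network(cmap, truth.tads)
        np.testing.assert_allclose(net.weights, net.weights.T)
        assert np.all(np.diag(net.weights) == 0)

    def test_non_tiling_tads_rejected(self, study_sim):
        cmap, truth = study_sim
        with pytest.raises(ValueError, match="tile"):
            build_tad_network(cmap, truth.tads[:-1])


class TestArrangementCost:
    def test_equal_weight_complete_graph_invariant(self):
        w = np.ones((5, 5))
        np.fill_diagonal(w, 0.0)
        rng = np.random.default_rng(0)
        costs = {arrangement_cost(w, rng.permutation(5)) for _ in range(10)}
        assert len(costs) == 1

    def test_path_in_path_order_costs_edge_sum(self):
        w = chain_network([2.0, 5.0, 1.0])
        assert arrangement_cost(w, np.arange(4)) == pytest.approx(8.0)

    def test_non_permutation_rejected(self):
        w = random_w(4, np.random.default_rng(0))
        with pytest.raises(ValueError, match="permutation"):
            arrangement_cost(w, np.array([0, 0, 1, 2]))


class TestMoveDeltas:
    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_deltas_match_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        w = random_w(n, rng)
        base = arrangement_cost(w, np.arange(n))
        P, rt = tilo._prefix(w)
        d_rev = tilo._reversal_deltas(w, P, rt)
        d_ins = tilo._reinsertion_deltas(w, P, rt)
        i, j = sorted(rng.choice(n, 2, replace=False))
        o = np.arange(n)
        o[i : j + 1] = o[i : j + 1][::-1]
        assert d_rev[i, j] == pytest.approx(arrangement_cost(w, o) - base, abs=1e-9)
        k, m = rng.choice(n, 2, replace=False)
        o2 = np.insert(np.delete(np.arange(n), k), m, k)
        assert d_ins[k, m] == pytest.approx(arrangement_cost(w, o2) - base, abs=1e-9)


class TestOrderNodes:
    def test_two_cliques_stay_contiguous(self):
        # interleaved cliques {0,2,4} and {1,3,5}, weak cross edges
        n = 6
        w = np.full((n, n), 0.01)
        for grp in ([0, 2, 4], [1, 3, 5]):
            for a in grp:
                for b in grp:
                    if a != b:
                        w[a, b] = 1.0
        np.fill_diagonal(w, 0.0)
        res = order_nodes(w, seed=0, restarts=5)
        parity = np.array([x % 2 for x in res.order])
        assert np.all(parity[:3] == parity[0]) and np.all(parity[3:] == parity[3])
        assert res.cost == pytest.approx(oracle_best_ordering(w).cost)

    def test_idempotent_on_optimal_ordering(self):
        rng = np.random.default_rng(12)
        w = random_w(6, rng)
        best = oracle_best_ordering(w)
        again, cost = tilo._descent(w, best.order)
        assert cost == pytest.approx(best.cost)

    def test_never_worse_than_start(self):
        rng = np.random.default_rng(3)
        w = random_w(15, rng)
        start = rng.permutation(15)
        _, cost = tilo._descent(w, start)
        assert cost <= arrangement_cost(w, start) + 1e-9

    def test_matches_oracle_on_small_instances(self):
        rng = np.random.default_rng(42)
        hits = 0
        for t in range(20):
            w = random_w(7, rng)
            best = oracle_best_ordering(w)
            got = order_nodes(w, seed=t, restarts=10)
            assert got.cost <= best.cost * 1.05 + 1e-12
            hits += got.cost == pytest.approx(best.cost)
        assert hits >= 18

    def test_deterministic_given_seed(self):
        w = random_w(12, np.random.default_rng(9))
        a = order_nodes(w, seed=5)
        b = order_nodes(w, seed=5)
        np.testing.assert_array_equal(a.order, b.order)


class TestOracle:
    def test_n2_identity(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(oracle_best_ordering(w).order, [0, 1])

    def test_n3_path_graph_path_order(self):
        w = chain_network([1.0, 1.0])
        res = oracle_best_ordering(w)
        assert res.cost == pytest.approx(2.0)
        assert res.order[1] == 1  # middle node stays central

    def test_refuses_large_n(self):
        with pytest.raises(ValueError, match="n=9"):
            oracle_best_ordering(np.zeros((9, 9)))


class TestCutProfile:
    def test_chain_515(self):
        w = chain_network([5.0, 1.0, 5.0])
        np.testing.assert_allclose(cut_profile(w, np.arange(4)), [5.0, 1.0, 5.0])

    def test_zero_network(self):
        np.testing.assert_allclose(cut_profile(np.zeros((5, 5)), np.arange(5)), 0.0)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        w = random_w(n, rng)
        order = rng.permutation(n)
        fast = cut_profile(w, order)
        A = w[np.ix_(order, order)]
        slow = np.array(
            [sum(A[k, l] for k in range(i) for l in range(i, n)) for i in range(1, n)]
        )
        np.testing.assert_allclose(fast, slow, atol=1e-10)


class TestPinchRatios:
    def test_515_single_minimum(self):
        assert pinch_ratios(np.array([5.0, 1.0, 5.0])) == [(2, pytest.approx(0.2))]

    def test_strictly_increasing_no_minima(self):
        assert pinch_ratios(np.array([1.0, 2.0, 3.0, 4.0])) == []

    def test_hand_computed_multivalley_table(self):
        # C = (8, 2, 6, 9, 1, 7, 3, 5): minima at t=1,4,6 ->
        # cuts 2, 5, 7 with rho = 2/8, 1/7, 3/5
        got = pinch_ratios(np.array([8.0, 2.0, 6.0, 9.0, 1.0, 7.0, 3.0, 5.0]))
        expect = [(2, 0.25), (5, 1.0 / 7.0), (7, 0.6)]
        assert [(i, pytest.approx(r)) for i, r in expect] == got

    def test_flat_profile_empty(self):
        assert pinch_ratios(np.full(6, 3.0)) == []


class TestSliceNetwork:
    def test_515_single_cut(self):
        w = chain_network([5.0, 1.0, 5.0])
        plan = slice_network(w, np.arange(4), tau=0.5)
        assert plan.cuts == [2]

    def test_tau_zero_no_cuts(self):
        w = chain_network([5.0, 1.0, 5.0])
        assert slice_network(w, np.arange(4), tau=0.0).cuts == []

    def test_min_size_blocks_tiny_segments(self):
        # valley right next to the end would create a 1-node segment
        w = chain_network([0.1, 5.0, 5.0, 5.0])
        plan = slice_network(w, np.arange(5), tau=0.9, min_size=2)
        assert 1 not in plan.cuts

    def test_multivalley_greedy_acceptance(self):
        w = chain_network([8.0, 2.0, 6.0, 9.0, 1.0, 7.0, 3.0, 5.0])
        plan = slice_network(w, np.arange(9), tau=0.5)
        assert plan.cuts == [2, 5]

    def test_planted_k4_cuts_at_cluster_borders(self, study_sim):
        cmap, truth = study_sim
        net = build_tad_network(cmap, truth.tads)
        W = net.weights
        b = np.median(W[np.triu_indices(net.n, 1)])
        Wc = np.clip(W - b, 0.0, None)
        ordering = order_nodes(Wc, seed=0, restarts=3)
        plan = slice_network(Wc, ordering, tau=0.5)
        assert len(plan.cuts) == 3
        # each segment is exactly one planted cluster
        edges = [0] + plan.cuts + [net.n]
        for s, e in zip(edges[:-1], edges[1:]):
            seg = truth.cluster_labels[ordering.order[s:e]]
            assert len(set(seg.tolist())) == 1


class TestTiloCluster:
    def test_zero_network_single_cluster(self):
        net = TADNetwork(weights=np.zeros((6, 6)), node_ids=np.arange(6))
        res = tilo_cluster(net, restarts=3)
        assert res.n_clusters == 1
        assert res.robustness == 1.0

    def test_planted_recovery_three_seeds(self):
        for s in (0, 1, 2):
            p = synthio.study_params(seed=s)
            cmap, truth = synthio.simulate_chromosome(p)
            res = tilo_cluster(cmap, truth.tads, seed=s, restarts=4)
            assert adjusted_rand_score(truth.cluster_labels, res.labels) >= 0.9

    def test_same_seed_identical_output(self, small_sim):
        cmap, truth = small_sim
        a = tilo_cluster(cmap, truth.tads, seed=3, restarts=3)
        b = tilo_cluster(cmap, truth.tads, seed=3, restarts=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.robustness == b.robustness

    def test_labels_canonical_by_genomic_first_appearance(self, small_sim):
        cmap, truth = small_sim
        res = tilo_cluster(cmap, truth.tads, seed=1, restarts=3)
        seen = []
        for l in res.labels:
            if l not in seen:
                seen.append(l)
        assert seen == sorted(seen)

    def test_block_structured_network_robustness_one(self):
        w = np.zeros((8, 8))
        for grp in (range(0, 4), range(4, 8)):
            for a in grp:
                for b in grp:
                    if a != b:
                        w[a, b] = 1.0
        net = TADNetwork(weights=w, node_ids=np.arange(8))
        res = tilo_cluster(net, restarts=4, baseline="none")
        assert res.robustness == 1.0
        assert res.n_clusters == 2

    def test_recovery_monotone_in_cluster_fold(self):
        aris = []
        for gamma in (1.0, 1.5, 2.0, 3.0):
            p = synthio.study_params(seed=13, cluster_fold=gamma)
            cmap, truth = synthio.simulate_chromosome(p)
            res = tilo_cluster(cmap, truth.tads, seed=13, restarts=3)
            aris.append(adjusted_rand_score(truth.cluster_labels, res.labels))
        assert aris == sorted(aris) or (aris[-1] >= 0.9 and aris[0] <= 0.1)
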