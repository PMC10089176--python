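import itertools
import math

import numpy as np
import pytest

from phylodisp.ctmc import (
    GeoModelParams,
    RateMatrix,
    build_rate_matrix,
    transition_probabilities,
)
from phylodisp.geodata import GeographicData
from phylodisp.histories import (
    ancestral_area_probabilities,
    count_dispersal_events,
    sample_branch_path_rejection,
    sample_branch_path_uniformization,
    sample_conditional_history,
)
from phylodisp.simulate import SimulationScenario, simulate_history_and_tips, simulate_tree
from phylodisp.tree import read_newick_tree


class TestBranchSampling:
    def test_zero_duration_equal_endpoints_no_events(self, two_state_Q):
        rng = np.random.default_rng(0)
        assert sample_branch_path_uniformization(two_state_Q.Q, 0.0, 0, 0, rng) == []

    def test_two_state_parity(self, two_state_Q):
        rng = np.random.default_rng(1)
        for _ in range(200):
            path = sample_branch_path_uniformization(two_state_Q.Q, 1.3, 0, 1, rng)
            assert len(path) % 2 == 1
            path = sample_branch_path_uniformization(two_state_Q.Q, 1.3, 0, 0, rng)
            assert len(path) % 2 == 0

    def test_paths_chain_consistently(self):
        rng = np.random.default_rng(2)
        params = GeoModelParams(False, np.arange(1.0, 7.0), np.ones(6, int), mu=2.0)
        Q = build_rate_matrix(params, 3).Q
        for _ in range(100):
            a, b = rng.integers(3), rng.integers(3)
            path = sample_branch_path_uniformization(Q, 0.8, int(a), int(b), rng)
            state, t_prev = int(a), 0.0
            for t, u, v in path:
                assert u == state and t >= t_prev and u != v
                state, t_prev = v, t
            assert state == int(b)

    def test_uniformization_matches_rejection_sampler(self, two_state_Q):
        """Conditional event-count distribution agrees between the
        uniformization sampler and brute-force rejection (3 SE)."""
        rng = np.random.default_rng(3)
        n = 4000
        uni = np.array([len(sample_branch_path_uniformization(
            two_state_Q.Q, 1.0, 0, 1, rng)) for _ in range(n)])
        rej = np.array([len(sample_branch_path_rejection(
            two_state_Q.Q, 1.0, 0, 1, rng)) for _ in range(n)])
        se = math.hypot(uni.std(ddof=1) / math.sqrt(n), rej.std(ddof=1) / math.sqrt(n))
        assert abs(uni.mean() - rej.mean()) < 3 * se

    def test_impossible_endpoint_raises(self):
        Q = np.zeros((2, 2))
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            sample_branch_path_uniformization(Q, 1.0, 0, 1, rng)


def exact_node_marginals(tree, data, Q, root_freqs=None):
    """Enumerate all internal-state assignments to get exact conditional
    node-state probabilities; oracle for sampled histories."""
    k = data.k
    if root_freqs is None:
        root_freqs = np.full(k, 1.0 / k)
    tip_state = data.tip_state_vector(tree)
    internal = [i for i in range(tree.n_nodes) if tree.children(i)]
    P = {n: transition_probabilities(Q, float(tree.branch_length[n]))
         for n in range(tree.n_nodes)}
    marg = np.zeros((tree.n_nodes, k))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        state = dict(zip(internal, assign))
        for n in range(tree.n_nodes):
            if tip_state[n] >= 0:
                state[n] = int(tip_state[n])
        p = root_freqs[state[tree.root]]
        for n in range(tree.n_nodes):
            if n != tree.root:
                p *= P[n][state[tree.parent[n]], state[n]]
        total += p
        for n, s in state.items():
            marg[n, s] += p
    return marg / total


class TestConditionalHistories:
    def setup_method(self):
        self.tree = read_newick_tree("((A:0.6,B:0.9):0.5,(C:0.8,D:0.4):0.7);")
        self.data = GeographicData(areas=("x", "y"),
                                   tip_area={"A": 0, "B": 1, "C": 0, "D": 1})
        params = GeoModelParams(True, np.ones(1), np.ones(1, int), mu=1.2)
        self.Q = build_rate_matrix(params, 2)

    def test_history_is_consistent_and_matches_tips(self):
        rng = np.random.default_rng(5)
        tip_state = self.data.tip_state_vector(self.tree)
        for _ in range(20):
            h = sample_conditional_history(self.tree, self.data, self.Q, rng=rng)
            h.validate()
            for node, s in enumerate(tip_state):
                if s >= 0:
                    assert h.node_state[node] == s

    def test_node_marginals_match_exact_conditionals(self):
        rng = np.random.default_rng(6)
        n = 4000
        hists = [sample_conditional_history(self.tree, self.data, self.Q, rng=rng)
                 for _ in range(n)]
        table = ancestral_area_probabilities(hists)
        exact = exact_node_marginals(self.tree, self.data, self.Q.Q)
        for node in range(self.tree.n_nodes):
            for a in range(2):
                p = exact[node, a]
                se = math.sqrt(max(p * (1 - p) / n, 1e-12))
                assert abs(table.loc[node, f"p_{a}"] - p) <= 3 * se + 1e-9

    def test_three_area_toy_marginals(self):
        tree = read_newick_tree("((A:0.5,B:0.7):0.4,C:1.1);")
        data = GeographicData(areas=("x", "y", "z"),
                              tip_area={"A": 0, "B": 1, "C": 2})
        params = GeoModelParams(True, np.array([1.0, 2.0, 0.5]),
                                np.ones(3, int), mu=1.0)
        Q = build_rate_matrix(params, 3)
        rng = np.random.default_rng(7)
        n = 3000
        hists = [sample_conditional_history(tree, data, Q, rng=rng)
                 for _ in range(n)]
        table = ancestral_area_probabilities(hists)
        exact = exact_node_marginals(tree, data, Q.Q)
        for node in range(tree.n_nodes):
            for a in range(3):
                p = exact[node, a]
                se = math.sqrt(max(p * (1 - p) / n, 1e-12))
                assert abs(table.loc[node, f"p_{a}"] - p) <= 3.5 * se + 1e-9

    def test_zero_likelihood_raises(self):
        params = GeoModelParams(True, np.ones(1), np.zeros(1, int), mu=1.0)
        Q = build_rate_matrix(params, 2)  # degenerate: no dispersal possible
        with pytest.raises(ValueError):
            sample_conditional_history(self.tree, self.data, Q,
                                       rng=np.random.default_rng(1))

    def test_minimum_events_when_all_areas_observed(self):
        rng = np.random.default_rng(8)
        tree = read_newick_tree("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        data = GeographicData(areas=("x", "y", "z"),
                              tip_area={"A": 0, "B": 1, "C": 2, "D": 0})
        params = GeoModelParams(True, np.ones(3), np.ones(3, int), mu=1.0)
        Q = build_rate_matrix(params, 3)
        for _ in range(50):
            h = sample_conditional_history(tree, data, Q, rng=rng)
            assert h.n_events >= 2  # k - 1 with all 3 areas at the tips


class TestSummaries:
    def test_rows_sum_to_one(self):
        tree = read_newick_tree("((A:1,B:1):0.5,C:1.5);")
        data = GeographicData(areas=("x", "y"), tip_area={"A": 0, "B": 0, "C": 1})
        params = GeoModelParams(True, np.ones(1), np.ones(1, int), mu=0.8)
        Q = build_rate_matrix(params, 2)
        rng = np.random.default_rng(9)
        hists = [sample_conditional_history(tree, data, Q, rng=rng)
                 for _ in range(200)]
        table = ancestral_area_probabilities(hists)
        np.testing.assert_allclose(
            table[["p_0", "p_1"]].sum(axis=1).to_numpy(), 1.0, atol=1e-12)

    def test_tiny_branches_pin_root_to_shared_tip_area(self):
        tree = read_newick_tree("(A:1e-8,B:1e-8);")
        data = GeographicData(areas=("x", "y"), tip_area={"A": 0, "B": 0})
        params = GeoModelParams(True, np.ones(1), np.ones(1, int), mu=1.0)
        Q = build_rate_matrix(params, 2)
        rng = np.random.default_rng(10)
        hists = [sample_conditional_history(tree, data, Q, rng=rng)
                 for _ in range(100)]
        table = ancestral_area_probabilities(hists)
        root = tree.root
        assert table.loc[root, "map_area"] == 0
        assert table.loc[root, "map_prob"] == pytest.approx(1.0)

    def test_event_free_histories_give_zero_matrix(self):
        tree = read_newick_tree("(A:1e-8,B:1e-8);")
        data = GeographicData(areas=("x", "y"), tip_area={"A": 0, "B": 0})
        params = GeoModelParams(True, np.ones(1), np.ones(1, int), mu=1.0)
        Q = build_rate_matrix(params, 2)
        rng = np.random.default_rng(11)
        hists = [sample_conditional_history(tree, data, Q, rng=rng)
                 for _ in range(150)]
        out = count_dispersal_events(hists)
        assert out["total_mean"] == 0.0
        np.testing.assert_array_equal(out["mean"], np.zeros((2, 2)))

    def test_source_percentages_sum_to_100(self):
        scen = SimulationScenario(n_tips=15, k=3, seed=12)
        tree = simulate_tree(scen)
        params = GeoModelParams(True, np.ones(3), np.ones(3, int),
                                mu=8.0 / tree.tree_length)
        Q = build_rate_matrix(params, 3)
        _, data = simulate_history_and_tips(tree, Q, root_area=0, rng=13)
        rng = np.random.default_rng(14)
        hists = [sample_conditional_history(tree, data, Q, rng=rng)
                 for _ in range(100)]
        out = count_dispersal_events(hists)
        with_events = [h for h in hists if h.n_events > 0]
        if with_events:
            assert out["per_source"]["pct_mean"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_unconditional_event_mean_matches_mu_T(self):
        """Prior histories (no conditioning): mean events = mu * T (3 SE)."""
        scen = SimulationScenario(n_tips=12, k=3, seed=15)
        tree = simulate_tree(scen)
        mu = 5.0 / tree.tree_length
        params = GeoModelParams(True, np.ones(3), np.ones(3, int), mu=mu)
        Q = build_rate_matrix(params, 3)
        rng = np.random.default_rng(16)
        counts = [simulate_history_and_tips(tree, Q, rng=rng)[0].n_events
                  for _ in range(600)]
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(np.mean(counts) - mu * tree.tree_length) < 3 * se

    def test_mismatched_trees_rejected(self):
        t1 = read_newick_tree("(A:1,B:1);")
        t2 = read_newick_tree("(A:1,B:1);")
        data = GeographicData(areas=("x", "y"), tip_area={"A": 0, "B": 0})
        params = GeoModelParams(True, np.ones(1), np.ones(1, int), mu=1.0)
        Q = build_rate_matrix(params, 2)
        h1 = sample_conditional_history(t1, data, Q, rng=np.random.default_rng(1))
        h2 = sample_conditional_history(t2, data, Q, rng=np.random.default_rng(1))
        with pytest.raises(ValueError):
            ancestral_area_probabilities([h1, h2])
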