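"""Node measures, rank aggregation and whole-brain graph assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aanconn.connectivity import ConnectivityMatrix
from aanconn.errors import ConfigError, ValidationError
from aanconn.metrics import (assemble_whole_brain, betweenness,
                             clustering_coefficient, degree,
                             group_degree_summary, hub_rank, hub_rank_delta,
                             node_metrics, rank_measures, relative_hub_rank)
from aanconn.synthetic import GenerativeSpec, generate_true_cp

from conftest import make_adjacency
from oracles import (brute_betweenness, brute_clustering, brute_degree,
                     random_adjacency)


def star(n):
    a = np.zeros((n, n), dtype=np.int8)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


class TestDegree:
    def test_star_center(self):
        assert degree(make_adjacency(star(5)), 0) == 4

    def test_isolated_node(self):
        assert degree(make_adjacency(np.zeros((3, 3))), 1) == 0

    def test_matches_edge_count_oracle(self, rng):
        a = random_adjacency(rng, 8, 0.4)
        adj = make_adjacency(a)
        for i in range(8):
            assert degree(adj, i) == brute_degree(a, i)

    def test_degree_sum_is_twice_edge_count(self, rng):
        a = random_adjacency(rng, 10, 0.3)
        assert degree(make_adjacency(a)).sum() == a.sum()


class TestClustering:
    def test_triangle_is_fully_clustered(self):
        a = 1 - np.eye(3, dtype=np.int8)
        assert clustering_coefficient(make_adjacency(a), 0) == 1.0

    def test_star_center_unclustered(self):
        assert clustering_coefficient(make_adjacency(star(5)), 0) == 0.0

    def test_low_degree_nodes_assigned_one(self):
        """Leaves and isolated nodes get CC = 1 so they cannot fake hubness."""
        cc = clustering_coefficient(make_adjacency(star(5)))
        assert (cc[1:] == 1.0).all()
        assert clustering_coefficient(make_adjacency(np.zeros((2, 2))), 0) == 1.0

    def test_matches_triangle_enumeration_oracle(self, rng):
        a = random_adjacency(rng, 7, 0.5)
        adj = make_adjacency(a)
        for i in range(7):
            assert clustering_coefficient(adj, i) == pytest.approx(
                brute_clustering(a, i))

    def test_complete_graph_all_one(self):
        a = 1 - np.eye(6, dtype=np.int8)
        assert (clustering_coefficient(make_adjacency(a)) == 1.0).all()


class TestBetweenness:
    def test_path_graph_middle_node(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
        b = betweenness(make_adjacency(a))
        np.testing.assert_allclose(b, [0.0, 1.0, 0.0])

    def test_complete_graph_all_zero(self):
        a = 1 - np.eye(4, dtype=np.int8)
        np.testing.assert_allclose(betweenness(make_adjacency(a)), 0.0)

    def test_matches_path_enumeration_oracle(self, rng):
        """Unnormalized, unordered-pair betweenness on random graphs,
        including disconnected ones."""
        for _ in range(25):
            n = int(rng.integers(3, 8))
            a = random_adjacency(rng, n, float(rng.uniform(0.2, 0.8)))
            got = betweenness(make_adjacency(a))
            np.testing.assert_allclose(got, brute_betweenness(a), atol=1e-9)


class TestRanks:
    def test_degree_rank_ascending(self):
        rd, _, _ = rank_measures([5, 2, 1], [0, 0, 0], [1, 1, 1])
        np.testing.assert_allclose(rd, [3, 2, 1])

    def test_clustering_rank_inverted(self):
        _, _, rcc = rank_measures([0, 0, 0], [0, 0, 0], [0.1, 0.5, 0.9])
        np.testing.assert_allclose(rcc, [3, 2, 1])

    def test_ties_get_mean_of_positions(self):
        _, rb, _ = rank_measures([0, 0, 0], [4, 4, 0], [0, 0, 0])
        np.testing.assert_allclose(rb, [2.5, 2.5, 1])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 5), min_size=2, max_size=12))
    def test_rank_sum_invariant_under_ties(self, values):
        """Mean-of-ties keeps sum(ranks) = N(N+1)/2 even with heavy ties."""
        n = len(values)
        rd, rb, rcc = rank_measures(values, values, values)
        for r in (rd, rb, rcc):
            assert r.sum() == pytest.approx(n * (n + 1) / 2)
            assert (1 <= r).all() and (r <= n).all()

    def test_hub_rank_is_mean_of_ranks(self):
        np.testing.assert_allclose(
            hub_rank(np.array([27.0]), np.array([27.0]), np.array([27.0])), 27)
        np.testing.assert_allclose(
            hub_rank(np.array([1.0]), np.array([1.0]), np.array([1.0])), 1)
        np.testing.assert_allclose(
            hub_rank(np.array([10.0]), np.array([20.0]), np.array([3.0])), 11.0)

    def test_relative_hub_rank_normalization(self):
        np.testing.assert_allclose(relative_hub_rank(np.array([27.0]), 27), 1.0)
        np.testing.assert_allclose(relative_hub_rank(np.array([1.0]), 27), 1 / 27)
        np.testing.assert_allclose(relative_hub_rank(np.array([42.5]), 85), 0.5)
        with pytest.raises(ConfigError):
            relative_hub_rank(np.array([1.0]), 0)

    def test_hub_rank_delta_antisymmetric(self, rng):
        idx = ["DR", "VTA", "LC_L"]
        a = pd.Series(rng.random(3), index=idx)
        b = pd.Series(rng.random(3), index=idx)
        pd.testing.assert_series_equal(hub_rank_delta(a, b),
                                       -hub_rank_delta(b, a))
        assert (hub_rank_delta(a, a) == 0).all()

    def test_hub_rank_delta_index_mismatch(self):
        a = pd.Series([0.1], index=["DR"])
        b = pd.Series([0.1], index=["VTA"])
        with pytest.raises(ValidationError):
            hub_rank_delta(a, b)

    def test_hub_rank_permutation_equivariance(self, rng):
        """Relabeling nodes permutes hub ranks identically."""
        a = random_adjacency(rng, 9, 0.4)
        m1 = node_metrics(make_adjacency(a))
        perm = rng.permutation(9)
        m2 = node_metrics(make_adjacency(a[np.ix_(perm, perm)],
                                         labels=[f"n{i}" for i in perm]))
        merged = m1.set_index("abbrev").loc[m2["abbrev"]]
        np.testing.assert_allclose(m2["hub_rank"].to_numpy(),
                                   merged["hub_rank"].to_numpy())


class TestWholeBrain:
    def test_85_node_assembly(self):
        spec = GenerativeSpec(n_cortical_targets=58, rng_seed=0)
        c = generate_true_cp(spec, alpha=0.9)
        adj = assemble_whole_brain(c, th=0.5)
        assert len(adj.labels) == 85
        # cortical-cortical block is structurally empty (target-only nodes)
        assert adj.a[27:, 27:].sum() == 0
        # hub seeds project to cortex above threshold
        i_dr = adj.labels.index("DR")
        assert adj.a[i_dr, 27:].sum() == 58

    def test_relative_ranks_comparable_across_sizes(self):
        spec = GenerativeSpec(n_cortical_targets=58, rng_seed=0)
        c = generate_true_cp(spec, alpha=0.9)
        whole = node_metrics(assemble_whole_brain(c, th=0.5))
        aan = node_metrics(assemble_whole_brain(
            ConnectivityMatrix(seeds=c.seeds, targets=list(c.seeds),
                               cp=c.seed_block()), th=0.5))
        assert whole["network_size"].iloc[0] == 85
        assert aan["network_size"].iloc[0] == 27
        rel_w = whole.set_index("abbrev")["relative_hub_rank"].loc[c.seeds]
        rel_a = aan.set_index("abbrev")["relative_hub_rank"].loc[c.seeds]
        delta = hub_rank_delta(rel_w, rel_a)
        assert delta.abs().max() <= 1.0


class TestGroupDegreeSummary:
    def test_single_subject_per_group_returns_own_degrees(self, rng):
        a = random_adjacency(rng, 5, 0.5)
        adj = make_adjacency(a)
        out = group_degree_summary({"s1": adj}, {"s1": "fetal"})
        np.testing.assert_array_equal(out.loc["fetal"].to_numpy(),
                                      adj.degree_vector())

    def test_identical_subjects_average_to_same(self, rng):
        adj = make_adjacency(random_adjacency(rng, 5, 0.5))
        out = group_degree_summary({"s1": adj, "s2": adj},
                                   {"s1": "adult", "s2": "adult"})
        np.testing.assert_array_equal(out.loc["adult"].to_numpy(),
                                      adj.degree_vector())

    def test_missing_subject_rejected(self, rng):
        adj = make_adjacency(random_adjacency(rng, 4, 0.5))
        with pytest.raises(ValidationError):
            group_degree_summary({"s1": adj}, {"s1": "fetal", "s2": "adult"})
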