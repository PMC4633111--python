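import networkx as nx
import numpy as np
import pytest

from morphnet.network import (
    AdjacencyMatrix,
    DisconnectedGraphWarning,
    binarize_by_sparsity,
    betweenness_normalized,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    identify_hubs,
    local_efficiency,
    maslov_random_reference,
    profile_similarity_uniqueness,
    small_world_metrics,
)
from morphnet.similarity import SimilarityMatrix

from conftest import random_graph
from oracles import (
    bf_betweenness,
    bf_clustering,
    bf_global_efficiency,
    bf_local_efficiency,
    bf_path_length,
)


def adj_from_edges(n, edges):
    a = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return a


TRIANGLE = adj_from_edges(3, [(0, 1), (1, 2), (0, 2)])
STAR4 = adj_from_edges(4, [(0, 1), (0, 2), (0, 3)])
PATH3 = adj_from_edges(3, [(0, 1), (1, 2)])
CYCLE4_DIAG = adj_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
K4 = adj_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])


class TestBinarize:
    def _toy(self):
        # pair similarities AB .9, AC .8, AD .7, BC .6, BD .5, CD .4
        e = np.full((4, 4), np.nan)
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.6, (1, 3): 0.5, (2, 3): 0.4}
        for (i, j), v in vals.items():
            e[i, j] = e[j, i] = v
        return SimilarityMatrix(entries=e, region_ids=[1, 2, 3, 4])

    def test_top_half_edges(self):
        adj = binarize_by_sparsity(self._toy(), 0.5)
        assert adj.n_edges == 3
        assert set(adj.edge_list()) == {(0, 1), (0, 2), (0, 3)}

    def test_paper_scale_edge_count(self):
        rng = np.random.default_rng(0)
        e = rng.uniform(0.01, 0.99, (90, 90))
        e = (e + e.T) / 2
        sm = SimilarityMatrix(entries=e, region_ids=list(range(1, 91)))
        adj = binarize_by_sparsity(sm, 0.23)
        assert adj.n_edges == round(0.23 * 90 * 89 / 2) == 921

    def test_degenerate_sparsities(self):
        with pytest.raises(ValueError):
            binarize_by_sparsity(self._toy(), 0.01)  # K = 0
        with pytest.raises(ValueError):
            binarize_by_sparsity(self._toy(), 0.999)  # K = all pairs

    def test_identical_edge_count_across_subjects(self):
        rng = np.random.default_rng(1)
        counts = set()
        for _ in range(5):
            e = rng.uniform(0, 1, (20, 20))
            e = (e + e.T) / 2
            sm = SimilarityMatrix(entries=e, region_ids=list(range(20)))
            counts.add(binarize_by_sparsity(sm, 0.3).n_edges)
        assert len(counts) == 1

    def test_tie_break_deterministic(self):
        e = np.full((4, 4), 0.5)
        np.fill_diagonal(e, np.nan)
        sm = SimilarityMatrix(entries=e, region_ids=[1, 2, 3, 4])
        adj = binarize_by_sparsity(sm, 0.5)
        # all tied: lexicographic (i, j) order keeps the first 3 pairs
        assert set(adj.edge_list()) == {(0, 1), (0, 2), (0, 3)}


class TestClustering:
    def test_triangle(self):
        assert clustering_coefficient(TRIANGLE)[1] == 1.0

    def test_star(self):
        assert clustering_coefficient(STAR4)[1] == 0.0

    def test_cycle_with_diagonal(self):
        per_node, cp = clustering_coefficient(CYCLE4_DIAG)
        np.testing.assert_allclose(per_node, [2 / 3, 1.0, 2 / 3, 1.0])
        assert cp == pytest.approx(5 / 6)


class TestPathLength:
    def test_path3(self):
        assert characteristic_path_length(PATH3) == pytest.approx(4 / 3)

    def test_complete(self):
        assert characteristic_path_length(K4) == 1.0

    def test_disconnected_warns_and_averages_reachable(self):
        two_edges = adj_from_edges(4, [(0, 1), (2, 3)])
        with pytest.warns(DisconnectedGraphWarning):
            lp = characteristic_path_length(two_edges)
        assert lp == 1.0

    def test_no_edges_error(self):
        with pytest.raises(ValueError):
            characteristic_path_length(np.zeros((3, 3), dtype=int))


class TestBetweenness:
    def test_star(self):
        nm = betweenness_normalized(STAR4)
        np.testing.assert_allclose(nm.betweenness, [3, 0, 0, 0])
        assert nm.mean_betweenness == pytest.approx(0.75)
        np.testing.assert_allclose(nm.normalized_betweenness, [4, 0, 0, 0])

    def test_complete_graph_undefined_normalization(self):
        nm = betweenness_normalized(K4)
        np.testing.assert_allclose(nm.betweenness, 0.0)
        assert np.isnan(nm.normalized_betweenness).all()

    def test_path3(self):
        nm = betweenness_normalized(PATH3)
        np.testing.assert_allclose(nm.betweenness, [0, 1, 0])
        np.testing.assert_allclose(nm.normalized_betweenness, [0, 3, 0])


class TestEfficiency:
    def test_global_complete(self):
        assert global_efficiency(K4) == 1.0

    def test_global_path3(self):
        assert global_efficiency(PATH3) == pytest.approx(5 / 6)

    def test_global_empty(self):
        assert global_efficiency(np.zeros((4, 4), dtype=int)) == 0.0

    def test_local_triangle(self):
        assert local_efficiency(TRIANGLE) == 1.0

    def test_local_path3(self):
        assert local_efficiency(PATH3) == 0.0

    def test_local_cycle_with_diagonal(self):
        # neighbor-subgraph efficiencies by enumeration: (5/6, 1, 5/6, 1)
        assert local_efficiency(CYCLE4_DIAG) == pytest.approx(11 / 12)


class TestBruteForceEquivalence:
    """Dual-route check: implementation vs naive enumeration, exact."""

    @pytest.mark.parametrize("seed", range(20))
    def test_random_6_node_graphs(self, seed):
        rng = np.random.default_rng(seed)
        a = random_graph(6, rng.uniform(0.2, 0.8), rng)
        self._check(a)

    def test_named_graphs(self):
        for a in (TRIANGLE, STAR4, PATH3, CYCLE4_DIAG, K4):
            self._check(a)

    @staticmethod
    def _check(a):
        per_node, cp = clustering_coefficient(a)
        o_node, o_cp = bf_clustering(a)
        np.testing.assert_allclose(per_node, o_node, atol=1e-12)
        assert cp == pytest.approx(o_cp, abs=1e-12)
        assert global_efficiency(a) == pytest.approx(bf_global_efficiency(a), abs=1e-12)
        assert local_efficiency(a) == pytest.approx(bf_local_efficiency(a), abs=1e-12)
        nm = betweenness_normalized(a)
        np.testing.assert_allclose(nm.betweenness, bf_betweenness(a), atol=1e-9)
        if a.sum() > 0:
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DisconnectedGraphWarning)
                    assert characteristic_path_length(a) == pytest.approx(
                        bf_path_length(a), abs=1e-12
                    )


class TestMaslov:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(0)
        a = random_graph(12, 0.3, rng)
        ref = maslov_random_reference(a, seed=1)
        np.testing.assert_array_equal(
            np.sort(ref.degrees()), np.sort(a.sum(axis=1))
        )
        # degrees preserved per node, not just as a multiset
        np.testing.assert_array_equal(ref.degrees(), a.sum(axis=1))

    def test_determinism(self):
        rng = np.random.default_rng(2)
        a = random_graph(10, 0.4, rng)
        r1 = maslov_random_reference(a, seed=7)
        r2 = maslov_random_reference(a, seed=7)
        np.testing.assert_array_equal(r1.a, r2.a)

    def test_many_trials_edge_count_and_mixing(self):
        rng = np.random.default_rng(3)
        a = random_graph(8, 0.5, rng)
        m = a.sum() // 2
        shared_fracs = []
        for t in range(1000):
            ref = maslov_random_reference(a, seed=t)
            assert ref.n_edges == m
            assert not np.diag(ref.a).any()
            shared = (ref.a & a).sum() / a.sum()
            shared_fracs.append(shared)
        assert min(shared_fracs) < 1.0  # rewiring actually moves edges

    def test_too_few_edges(self):
        with pytest.raises(ValueError):
            maslov_random_reference(adj_from_edges(3, [(0, 1)]), seed=0)

    def test_ensemble_mean_degree_deviation_zero(self):
        rng = np.random.default_rng(4)
        a = random_graph(15, 0.3, rng)
        devs = [
            np.abs(maslov_random_reference(a, seed=s).degrees() - a.sum(axis=1)).sum()
            for s in range(100)
        ]
        assert sum(devs) == 0


class TestSmallWorld:
    def test_complete_graph_rigid(self):
        gm = small_world_metrics(K4, n_random=10, seed=0)
        assert gm.gamma == 1.0
        assert gm.lambda_ == 1.0
        assert gm.sigma == 1.0

    def test_watts_strogatz_sigma_above_one(self):
        g = nx.watts_strogatz_graph(90, 20, 0.1, seed=42)
        a = nx.to_numpy_array(g, dtype=int)
        gm = small_world_metrics(a, n_random=20, seed=0)
        assert gm.sigma > 1.0
        assert gm.gamma > 1.0

    def test_sigma_internal_consistency(self):
        rng = np.random.default_rng(5)
        a = random_graph(20, 0.3, rng)
        gm = small_world_metrics(a, n_random=10, seed=3)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lambda_, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_ws_gamma_lambda_ranges(self, seed):
        g = nx.watts_strogatz_graph(90, 20, 0.1, seed=seed)
        a = nx.to_numpy_array(g, dtype=int)
        gm = small_world_metrics(a, n_random=10, seed=seed)
        assert gm.gamma >= 1.0
        assert 0.9 < gm.lambda_ < 1.5

    def test_n_random_validation(self):
        with pytest.raises(ValueError):
            small_world_metrics(K4, n_random=0)


class TestHubs:
    def test_hand_example(self):
        hubs, mean_b, threshold = identify_hubs(np.array([[1.0, 1.0, 1.0, 5.0]]))
        assert threshold == pytest.approx(4.0)
        assert hubs == [3]

    def test_all_equal_no_hubs(self):
        hubs, _, _ = identify_hubs(np.array([[1.0, 1.0, 1.0, 1.0]]))
        assert hubs == []

    def test_single_subject_reduces_to_profile(self):
        profile = np.array([0.5, 0.7, 3.0, 0.8])
        h1, _, _ = identify_hubs(profile)
        h2, _, _ = identify_hubs(profile[np.newaxis, :])
        assert h1 == h2

    def test_cross_subject_mean(self):
        b = np.array([[1.0, 1.0, 1.0, 4.0], [1.0, 1.0, 1.0, 6.0]])
        hubs, mean_b, threshold = identify_hubs(b, region_ids=[10, 20, 30, 40])
        np.testing.assert_allclose(mean_b, [1, 1, 1, 5])
        assert hubs == [40]

    def test_single_node_error(self):
        with pytest.raises(ValueError):
            identify_hubs(np.array([[3.0]]))


class TestProfileScores:
    def test_identical_profiles(self):
        p = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), (3, 1))
        s = profile_similarity_uniqueness(p)
        np.testing.assert_allclose(s.similarity_raw, 1.0)
        np.testing.assert_allclose(s.uniqueness_raw, 0.0)
        np.testing.assert_allclose(s.similarity, 1.0)
        np.testing.assert_allclose(s.uniqueness, 0.0)

    def test_anticorrelated_subject(self):
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        flipped = 2 * base.mean() - base  # exact negative about the mean
        p = np.vstack([flipped, base, base])
        s = profile_similarity_uniqueness(p)
        assert s.uniqueness_raw[0] == pytest.approx(2.0)
        assert s.uniqueness[0] == pytest.approx(1.0)
        assert s.similarity_raw[0] == pytest.approx(-1.0)

    def test_two_subject_complement(self):
        rng = np.random.default_rng(6)
        p = rng.random((2, 10))
        s = profile_similarity_uniqueness(p)
        for m in range(2):
            assert s.uniqueness_raw[m] == pytest.approx(1 - s.similarity_raw[m])

    def test_zero_variance_error(self):
        p = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="subject index 0"):
            profile_similarity_uniqueness(p)

    def test_ranges(self):
        rng = np.random.default_rng(7)
        s = profile_similarity_uniqueness(rng.random((6, 12)))
        assert ((s.similarity_raw >= -1) & (s.similarity_raw <= 1)).all()
        assert ((s.uniqueness_raw >= 0) & (s.uniqueness_raw <= 2)).all()
        assert ((s.similarity >= 0) & (s.similarity <= 1)).all()
        assert ((s.uniqueness >= 0) & (s.uniqueness <= 1)).all()


class TestAdjacencyValidation:
    def test_rejects_asymmetric(self):
        a = np.zeros((3, 3), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError):
            AdjacencyMatrix(a=a, sparsity=0.3)

    def test_rejects_self_loops(self):
        a = np.eye(3, dtype=int)
        with pytest.raises(ValueError):
            AdjacencyMatrix(a=a, sparsity=0.3)
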