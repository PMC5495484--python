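import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from influmax.aco import (
    FAST_PRESET,
    AcoParams,
    construct_solution,
    exhaustive_imp,
    greedy_imp,
    hill_climb,
    pheromone_update,
    rank_influence,
    run_imp,
)
from influmax.diffusion import DiffusionScorer
from influmax.synthetic import (
    PlantedGraphSpec,
    planted_influencer_graph,
    random_weighted_digraph,
)

TINY = AcoParams(n_ants=8, n_restarts=2, local_steps=4)


class TestConstructSolution:
    def test_uniform_weights_give_uniform_subsets(self):
        # symmetry Monte-Carlo: equal u and r must make every node equally
        # likely; chi-square on selection frequencies over 10,000 draws
        rng = np.random.default_rng(0)
        n, k, draws = 8, 3, 10_000
        counts = np.zeros(n)
        u = np.ones(n)
        r = np.full(n, 0.5)
        for _ in range(draws):
            counts[construct_solution(u, r, k, rng)] += 1
        expected = draws * k / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(chi2, df=n - 1)
        assert p > 0.01

    def test_zero_weight_node_never_sampled(self):
        rng = np.random.default_rng(1)
        u = np.array([1.0, 0.0, 1.0, 1.0])
        r = np.full(4, 0.5)
        for _ in range(200):
            assert 1 not in construct_solution(u, r, 2, rng)

    def test_k_equals_n_returns_all(self):
        rng = np.random.default_rng(2)
        out = construct_solution(np.ones(5), np.full(5, 0.5), 5, rng)
        assert sorted(out) == list(range(5))

    def test_all_zero_falls_back_to_uniform(self):
        rng = np.random.default_rng(3)
        out = construct_solution(np.zeros(6), np.zeros(6), 3, rng)
        assert len(set(out.tolist())) == 3

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            construct_solution(np.ones(3), np.ones(3), 4, np.random.default_rng(0))


class TestHillClimb:
    def test_zero_steps_returns_input(self):
        g = random_weighted_digraph(10, 25, 0)
        scorer = DiffusionScorer(g)
        nodes = np.array([0, 1])
        out, score = hill_climb(nodes, scorer, 0, np.random.default_rng(0))
        assert sorted(out) == [0, 1]
        assert score == scorer.score_indices([0, 1])

    def test_score_never_decreases(self):
        for seed in range(10):
            g = random_weighted_digraph(12, 30, seed)
            scorer = DiffusionScorer(g)
            rng = np.random.default_rng(seed)
            start = np.array([0, 1, 2])
            before = scorer.score_indices(start)
            _, after = hill_climb(start, scorer, 16, rng)
            assert after >= before

    def test_finds_unique_improving_swap(self):
        # one strong hub and nine weak spokes: swapping any non-hub member
        # for the hub is the unique improvement
        g = nx.DiGraph()
        for i in range(1, 10):
            g.add_edge("hub", f"s{i}", weight=1.0)
        scorer = DiffusionScorer(g)
        hub = scorer.model.index["hub"]
        others = [i for i in range(10) if i != hub]
        found = 0
        for seed in range(40):
            out, score = hill_climb(
                np.array(others[:1]), scorer, 32, np.random.default_rng(seed)
            )
            found += hub in out
        assert found >= 38


class TestPheromoneUpdate:
    def test_fixed_point(self):
        r = np.array([1.0, 0.0, 1.0])
        out = pheromone_update(r, (1, 0, 0), 0.2, np.array([0, 2]), np.array([0]), np.array([0]))
        np.testing.assert_allclose(out, r)

    def test_full_learning_rate_jumps_to_average(self):
        r = np.array([0.3, 0.7])
        out = pheromone_update(r, (0.5, 0.5, 0.0), 1.0, np.array([0]), np.array([1]), np.array([1]))
        np.testing.assert_allclose(out, [0.5, 0.5])

    def test_single_step_arithmetic(self):
        r = np.full(4, 0.5)
        out = pheromone_update(r, (1, 0, 0), 0.2, np.array([2]), np.array([2]), np.array([2]))
        assert out[2] == pytest.approx(0.6)
        assert out[0] == pytest.approx(0.4)

    def test_hypercube_containment_over_many_updates(self):
        rng = np.random.default_rng(0)
        r = rng.random(20)
        for _ in range(500):
            members = [rng.choice(20, 5, replace=False) for _ in range(3)]
            f = rng.dirichlet(np.ones(3))
            r = pheromone_update(r, tuple(f), 0.3, *members)
            assert np.all(r >= 0) and np.all(r <= 1)


class TestRunImp:
    def test_k1_matches_argmax_over_singletons(self):
        g = random_weighted_digraph(8, 20, 5)
        scorer = DiffusionScorer(g)
        best = max((scorer.score_indices([i]) for i in range(8)))
        sol = run_imp(g, 1, TINY, seed=0, scorer=scorer)
        assert sol.score.omega == best.omega

    def test_small_instances_match_exhaustive(self):
        matched = total = 0
        for seed in range(10):
            g = random_weighted_digraph(12, 30, seed)
            scorer = DiffusionScorer(g)
            for k in (1, 2):
                total += 1
                aco = run_imp(g, k, FAST_PRESET, seed=seed, scorer=scorer)
                exact = exhaustive_imp(g, k, scorer=scorer)
                matched += aco.score.omega == exact.score.omega
        assert matched >= total - 1

    def test_same_seed_same_solution(self):
        g = random_weighted_digraph(15, 40, 3)
        a = run_imp(g, 3, TINY, seed=11)
        b = run_imp(g, 3, TINY, seed=11)
        assert a.nodes == b.nodes
        assert a.score == b.score

    def test_k_zero_and_empty_graph(self):
        g = random_weighted_digraph(5, 10, 0)
        assert run_imp(g, 0, TINY, seed=0).score.omega == 0
        assert run_imp(nx.DiGraph(), 0, TINY, seed=0).score.omega == 0

    def test_k_exceeding_nodes_rejected(self):
        g = random_weighted_digraph(4, 6, 0)
        with pytest.raises(ValueError):
            run_imp(g, 9, TINY, seed=0)


class TestExhaustiveAndGreedy:
    def test_chain_k1_optimum_is_head(self, chain_graph):
        sol = exhaustive_imp(chain_graph, 1)
        assert sol.nodes == {"a"}
        assert sol.score.omega == 2

    def test_k_equals_n_returns_everything(self):
        g = random_weighted_digraph(5, 12, 1)
        sol = exhaustive_imp(g, 5)
        assert sol.nodes == set(g.nodes)

    def test_guard_rejects_huge_enumerations(self):
        g = random_weighted_digraph(40, 100, 0)
        with pytest.raises(ValueError):
            exhaustive_imp(g, 15, guard=1000)

    def test_greedy_selects_disjoint_star_hubs(self):
        g = nx.DiGraph()
        for hub, fanout in (("h5", 5), ("h3", 3), ("h2", 2)):
            for i in range(fanout):
                g.add_edge(hub, f"{hub}leaf{i}", weight=1.0)
        sol = greedy_imp(g, 2)
        assert sol.nodes == {"h5", "h3"}
        assert sol.score.omega == 8

    def test_greedy_never_beats_exhaustive(self):
        for seed in range(8):
            g = random_weighted_digraph(10, 25, seed)
            scorer = DiffusionScorer(g)
            assert (
                greedy_imp(g, 2, scorer=scorer).score.omega
                <= exhaustive_imp(g, 2, scorer=scorer).score.omega
            )

    def test_greedy_k_zero(self):
        g = random_weighted_digraph(5, 10, 0)
        assert greedy_imp(g, 0).score.omega == 0

    def test_exhaustive_equals_greedy_on_disjoint_stars(self):
        g = nx.DiGraph()
        for hub, fanout in (("a", 4), ("b", 3), ("c", 2)):
            for i in range(fanout):
                g.add_edge(hub, f"{hub}{i}", weight=1.0)
        for k in (1, 2, 3):
            assert greedy_imp(g, k).score.omega == exhaustive_imp(g, k).score.omega


class TestRankInfluence:
    def test_counts_bounded_by_runs(self):
        g, roots = planted_influencer_graph(PlantedGraphSpec(n_influencers=2, depth=1))
        table = rank_influence(g, range(1, 4), reps=2, params=TINY, seed=0)
        assert (table["count"] <= 6).all()
        assert (table["count"] >= 0).all()

    def test_planted_influencers_rank_top(self):
        g, roots = planted_influencer_graph(PlantedGraphSpec())
        table = rank_influence(g, range(1, 6), reps=2, params=FAST_PRESET, seed=1)
        assert set(table.head(3)["node"]) == set(roots)

    def test_seeded_determinism(self):
        g = random_weighted_digraph(10, 30, 2)
        a = rank_influence(g, range(1, 4), reps=1, params=TINY, seed=5)
        b = rank_influence(g, range(1, 4), reps=1, params=TINY, seed=5)
        assert a.equals(b)

    def test_k_above_graph_size_rejected(self):
        g = random_weighted_digraph(4, 8, 0)
        with pytest.raises(ValueError):
            rank_influence(g, range(1, 10), reps=1, params=TINY, seed=0)
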