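"""Ecosystem, genetic algorithm, 3x3 comparison battery and analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from numerosense import evolife
from numerosense.evolife import (
    Agent,
    Ecosystem,
    EvoConfig,
    GreedyComparisonPolicy,
    GreedyForagerPolicy,
    Population,
    RandomPolicy,
    analyze_hidden_units,
    collection_rate,
    comparison_battery,
    distance_size_effects,
    encode_food,
    policy_comparison_battery,
    sense,
    simulate_foraging,
    step_agent,
)

SMALL = EvoConfig(grid_side=20, n_agents=12, burn_in=20)


@pytest.fixture()
def eco():
    return Ecosystem.initialize(SMALL, seed=5)


class TestEncodeFood:
    def test_extremes(self):
        rng = np.random.default_rng(0)
        assert encode_food(0, rng).sum() == 0
        assert encode_food(9, rng).sum() == 9

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            encode_food(10, np.random.default_rng(0))

    def test_exact_count_and_uniform_positions(self):
        rng = np.random.default_rng(1)
        draws = np.stack([encode_food(4, rng) for _ in range(10_000)])
        assert (draws.sum(axis=1) == 4).all()
        freq = draws.mean(axis=0)
        assert np.allclose(freq, 4 / 9, atol=0.02)

    def test_batched_encoder_matches_contract(self):
        rng = np.random.default_rng(2)
        values = rng.integers(0, 10, size=(50, 4))
        bits = evolife._encode_batch(values, rng)
        assert np.array_equal(bits.sum(axis=-1), values)


class TestSensing:
    def test_sense_composition(self, eco):
        agent = eco.agent(0)
        eco.population.pos[0] = (10, 10)
        eco.population.heading[0] = 0  # facing north
        eco.grid[:, :] = 0
        eco.grid[10, 10] = 3          # current cell
        eco.grid[9, 9] = 5            # front-left
        eco.grid[9, 10] = 0           # front
        eco.grid[9, 11] = 7           # front-right
        obs = sense(eco, agent)
        counts = obs.reshape(4, 9).sum(axis=1)
        assert list(counts) == [3, 5, 0, 7]

    def test_empty_neighbourhood_zero_vector(self, eco):
        eco.grid[:, :] = 0
        assert sense(eco, eco.agent(0)).sum() == 0

    def test_toroidal_wrap(self, eco):
        eco.population.pos[0] = (0, 0)
        eco.population.heading[0] = 0
        eco.grid[:, :] = 0
        eco.grid[19, 19] = 4          # front-left wraps around both axes
        obs = sense(eco, eco.agent(0))
        assert obs.reshape(4, 9).sum(axis=1)[1] == 4


class TestStepAgent:
    def _force_action(self, eco, idx, action):
        pop = eco.population
        pop.w_out[idx] = 0.0
        pop.b_out[idx] = 0.0
        pop.b_out[idx, action] = 5.0

    def test_forced_eat_transfers_and_empties(self, eco):
        self._force_action(eco, 0, 3)
        pop = eco.population
        pop.pos[0] = (4, 4)
        eco.grid[4, 4] = 5
        before = pop.collected[0]
        action = step_agent(eco.agent(0), np.zeros(36), ecosystem=eco)
        assert action == "eat"
        assert pop.collected[0] == before + 5
        assert eco.grid[4, 4] == 0

    def test_forced_forward_moves_toroidally(self, eco):
        self._force_action(eco, 1, 2)
        pop = eco.population
        pop.pos[1] = (0, 7)
        pop.heading[1] = 0
        step_agent(eco.agent(1), np.zeros(36), ecosystem=eco)
        assert tuple(pop.pos[1]) == (19, 7)   # wrapped across the top edge

    def test_turns_change_heading_only(self, eco):
        self._force_action(eco, 2, 0)
        pop = eco.population
        pop.pos[2] = (3, 3)
        pop.heading[2] = 0
        step_agent(eco.agent(2), np.zeros(36), ecosystem=eco)
        assert pop.heading[2] == 3
        assert tuple(pop.pos[2]) == (3, 3)


class TestFitness:
    def test_rate_arithmetic(self):
        assert collection_rate(12, 100) == pytest.approx(0.12)
        assert collection_rate(0, 50) == 0.0

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            collection_rate(3, 0)

    def test_agent_lifetime_fitness(self, eco):
        pop = eco.population
        pop.collected[0] = 6.0
        pop.age[0] = 30
        assert eco.agent(0).fitness() == pytest.approx(0.2)
        with pytest.raises(ValueError):
            eco.agent(0).fitness(window=100)

    def test_greedy_forager_beats_random(self):
        greedy, random_ = [], []
        for seed in range(20):
            greedy.append(simulate_foraging(GreedyForagerPolicy(), 600,
                                            seed=seed))
            random_.append(simulate_foraging(RandomPolicy(), 600, seed=seed))
        assert np.mean(greedy) > np.mean(random_)
        assert sum(g > r for g, r in zip(greedy, random_)) >= 16


class TestEvolution:
    def test_zero_iterations_population_unchanged(self, eco):
        before = eco.population.w_in.copy()
        evolife.evolve(eco, 0)
        assert np.array_equal(eco.population.w_in, before)

    def test_population_size_invariant(self, eco):
        for _ in range(200):
            evolife.update(eco)
            assert eco.population.size == SMALL.n_agents

    def test_crossover_degenerate_identical_parents(self):
        cfg = EvoConfig(mutation_rate=0.0)
        rng = np.random.default_rng(9)
        genome = rng.normal(size=(4, 6))
        child = evolife._crossover_mutate(genome, genome.copy(), cfg, rng)
        assert np.array_equal(child, genome)

    def test_full_run_determinism(self):
        grids, collected = [], []
        for _ in range(2):
            e = Ecosystem.initialize(SMALL, seed=77)
            evolife.evolve(e, 300)
            grids.append(e.grid.copy())
            collected.append(e.population.collected.copy())
        assert np.array_equal(grids[0], grids[1])
        assert np.array_equal(collected[0], collected[1])

    def test_food_values_stay_in_range(self, eco):
        for _ in range(300):
            evolife.update(eco)
        assert eco.grid.min() >= 0 and eco.grid.max() <= 9

    def test_food_bookkeeping_conserves(self):
        """Without regrowth, collected food equals food removed from grid."""
        cfg = EvoConfig(grid_side=20, n_agents=12, burn_in=10**9,
                        regrow_delay=10_000)
        e = Ecosystem.initialize(cfg, seed=8)
        start = e.grid.sum()
        for _ in range(400):
            evolife.update(e)
        assert e.population.collected.sum() == start - e.grid.sum()


class TestComparisonBattery:
    def test_trial_count_is_3600(self):
        pop = Population.random(EvoConfig(n_agents=2), np.random.default_rng(3))
        trials = comparison_battery(pop, agent_indices=[0], repetitions=50,
                                    rng=np.random.default_rng(4))
        assert len(trials) == 3600
        pairs = trials.groupby(["left_value", "right_value"]).size()
        assert len(pairs) == 72 and (pairs == 50).all()

    def test_values_always_distinct_and_correct_flag(self):
        pop = Population.random(EvoConfig(n_agents=1),
                                np.random.default_rng(5))
        trials = comparison_battery(pop, repetitions=3,
                                    rng=np.random.default_rng(6))
        assert (trials.left_value != trials.right_value).all()
        done = trials[~trials.timeout]
        picked = np.where(done.chosen == "left", done.left_value,
                          done.right_value)
        other = np.where(done.chosen == "left", done.right_value,
                         done.left_value)
        assert ((picked > other) == done.correct).all()

    def test_oracle_policy_perfect_accuracy(self):
        trials = policy_comparison_battery(GreedyComparisonPolicy(),
                                           repetitions=3,
                                           rng=np.random.default_rng(7))
        assert not trials.timeout.any()
        assert trials.correct.all()
        assert (trials.rt == 4).all()

    def test_random_policy_at_chance(self):
        trials = policy_comparison_battery(RandomPolicy(), repetitions=20,
                                           rng=np.random.default_rng(8))
        done = trials[~trials.timeout]
        acc = done.correct.mean()
        se = np.sqrt(0.25 / len(done))
        assert abs(acc - 0.5) <= 2 * se + 0.01


class TestDistanceSizeEffects:
    def test_hand_built_tally(self):
        trials = pd.DataFrame({
            "agent": 0,
            "left_value": [1, 1, 2, 5, 5, 9],
            "right_value": [2, 3, 1, 9, 1, 1],
            "chosen": ["right"] * 6,
            "correct": [True, True, False, True, False, False],
            "rt": [2, 4, 6, 2, 10, 2],
            "timeout": [False] * 6,
        })
        by_distance, by_size = distance_size_effects(trials)
        d1 = by_distance[by_distance.distance == 1].iloc[0]
        assert d1.n_trials == 2 and d1.accuracy == 0.5 and d1.mean_rt == 4.0
        s9 = by_size[by_size["size"] == 9].iloc[0]
        assert s9.n_trials == 2 and s9.accuracy == 0.5

    def test_all_correct_flat_accuracy(self):
        trials = pd.DataFrame({
            "agent": 0, "left_value": [1, 1, 1], "right_value": [2, 3, 4],
            "chosen": "right", "correct": True, "rt": 3, "timeout": False,
        })
        by_distance, _ = distance_size_effects(trials)
        assert (by_distance.accuracy == 1.0).all()

    def test_chance_proportion_random_population(self):
        pop = Population.random(EvoConfig(n_agents=6),
                                np.random.default_rng(10))
        trials = comparison_battery(pop, repetitions=10,
                                    rng=np.random.default_rng(11))
        prop = evolife.chance_proportion(trials)
        assert 0.0 <= prop <= 1.0


class TestHiddenUnitAnalysis:
    def _population_with_planted_units(self):
        cfg = EvoConfig(n_agents=1)
        pop = Population.random(cfg, np.random.default_rng(12))
        pop.hidden_size[0] = 3
        pop.w_rec[0] = 0.0
        pop.b_hid[0] = 0.0
        pop.w_in[0] = 0.0
        pop.w_in[0, 0, 18:27] = 0.3    # sums the front-cell block: increasing
        pop.w_in[0, 1, 18:27] = -0.3   # decreasing
        # unit 2: constant (no input drive)
        return pop

    def test_planted_monotone_units(self):
        pop = self._population_with_planted_units()
        table, curves = analyze_hidden_units(pop, 0, repetitions=200,
                                             rng=np.random.default_rng(13))
        assert table.profile[0] == "monotone_increasing"
        assert table.profile[1] == "monotone_decreasing"
        assert table.profile[2] == "none"
        assert curves.shape == (9, 3)

    def test_rank_correlation_matches_manual_spearman(self):
        pop = self._population_with_planted_units()
        table, curves = analyze_hidden_units(pop, 0, repetitions=50,
                                             rng=np.random.default_rng(14))
        values = np.arange(1, 10)
        for u in (0, 1):
            rx = stats.rankdata(values)
            ry = stats.rankdata(curves[:, u])
            manual = np.corrcoef(rx, ry)[0, 1]
            assert table.spearman_rho[u] == pytest.approx(manual, abs=1e-10)
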