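"""The four-phase per-iteration scheduler and its bookkeeping."""

import math

import numpy as np
import pytest

from nutrilat import (FEEDING, SEARCHING, CompetitionConfig, Environment,
                      Population, choose_food_phase, eat_phase, fitness_phase,
                      leave_phase, leave_probability, run_generation)
from conftest import competition


def fresh_pop(n=150, k=1.0, mu=2.0):
    return Population.initial(np.full(n, k), mu=mu)


class TestChooseFood:
    def test_free_access_places_everyone_without_contests(self, mild_env, rng):
        pop = fresh_pop()
        choose_food_phase(pop, mild_env, competition(0.0), rng)
        assert np.all(pop.status == FEEDING)
        assert pop.contests_involved.sum() == 0

    def test_contest_bookkeeping_identity(self, mild_env, rng):
        """Every contest involves exactly two parties and one winner, so
        summed involvement is twice summed wins."""
        pop = fresh_pop()
        cfg = competition(0.767)
        for _ in range(30):
            run_generation_step(pop, mild_env, cfg, rng)
        total = pop.contests_won.sum()
        assert total > 0
        assert pop.contests_involved.sum() == 2 * total
        assert np.all(pop.contests_won <= pop.contests_involved)
        assert np.all(pop.contests_initiated <= pop.contests_involved)

    def test_equal_fitness_contest_is_fair(self):
        """With one slot and two equally fit individuals, the second to act
        displaces the first with empirical probability 1/2."""
        env = Environment.from_ratios([1.0])
        cfg = CompetitionConfig(0.5, 1, 2)  # capacity = 1
        rng = np.random.default_rng(99)
        displaced = 0
        trials = 10**4
        for _ in range(trials):
            pop = fresh_pop(n=2)
            choose_food_phase(pop, env, cfg, rng)
            assert pop.iters_displaced.sum() == 1  # exactly one loser
            displaced += pop.iters_displaced[0]
        assert displaced / trials == pytest.approx(0.5, abs=0.01)

    def test_empty_food_list_rejected(self):
        with pytest.raises(ValueError):
            Environment.from_ratios([])


def run_generation_step(pop, env, cfg, rng, phi=2.0, mu=2.0):
    choose_food_phase(pop, env, cfg, rng)
    eat_phase(pop, env, phi, rng)
    fitness_phase(pop, env, mu, rng)
    leave_phase(pop, env, phi, rng)


class TestEat:
    def test_balanced_rail_moves_phi_along_diagonal(self, mild_env, rng):
        pop = fresh_pop(n=1)
        pop.status[0] = FEEDING
        pop.food[0] = 1  # the V=1 rail
        eat_phase(pop, mild_env, phi=2.0)
        assert pop.x[0] == pytest.approx(math.sqrt(2))
        assert pop.y[0] == pytest.approx(math.sqrt(2))
        assert pop.feed_events[0] == 1
        assert pop.beta_sum[0] == pytest.approx(0.0)

    def test_compromise_point_records_beta_without_movement(self, mild_env):
        pop = fresh_pop(n=1)
        pop.status[0] = FEEDING
        pop.food[0] = 2  # V=2 rail
        rail = mild_env.foods[2].rail_angle
        # place at the foot of the perpendicular from the IT
        d = 500 * math.sqrt(2) * math.cos(rail - math.pi / 4)
        pop.x[0], pop.y[0] = d * math.cos(rail), d * math.sin(rail)
        eat_phase(pop, mild_env, phi=2.0)
        assert pop.x[0] == pytest.approx(d * math.cos(rail), abs=1e-9)
        assert pop.feed_events[0] == 1
        assert pop.beta_sum[0] > 0

    def test_displaced_individual_does_not_move(self, mild_env):
        pop = fresh_pop(n=2)
        pop.status[:] = (FEEDING, 2)  # second is DISPLACED
        pop.food[0] = 0
        eat_phase(pop, mild_env, phi=2.0)
        assert pop.x[1] == 0.0 and pop.y[1] == 0.0
        assert pop.feed_events[1] == 0


class TestFitness:
    def test_natal_state_fitness(self, mild_env):
        pop = fresh_pop(n=3)
        fitness_phase(pop, mild_env, mu=2.0)
        assert pop.fit == pytest.approx(np.exp(-2.0))

    def test_fitness_depends_only_on_distance(self, mild_env):
        pop = fresh_pop(n=3)
        pop.x[:] = (500.0, 400.0, 500.0 - 100 / math.sqrt(2))
        pop.y[:] = (400.0, 500.0, 500.0 - 100 / math.sqrt(2))
        fitness_phase(pop, mild_env, mu=2.0)
        assert pop.fit[0] == pytest.approx(pop.fit[1])
        assert pop.fit[2] == pytest.approx(pop.fit[0])
        pop.x[0], pop.y[0] = 500.0, 500.0
        fitness_phase(pop, mild_env, mu=2.0)
        assert pop.fit[0] == 1.0


class TestLeave:
    def test_leave_probability_boundaries(self):
        # K=0 on a rail orthogonal to the ideal: certain departure
        assert leave_probability(0.0, 0.0, math.pi / 2, 10.0, 2.0) == 1.0
        # K=1 with appetite >= phi: never leaves a food it can exploit
        assert leave_probability(1.0, 0.5, 0.7, 5.0, 2.0) == 0.0
        # K=1 at the compromise point (A=0): certain departure
        assert leave_probability(1.0, 0.5, 0.7, 0.0, 2.0) == 1.0

    def test_high_k_far_from_target_stays(self, mild_env, rng):
        pop = fresh_pop(n=50, k=1.0)
        pop.status[:] = FEEDING
        pop.food[:] = 1  # balanced rail, far from IT: P_leave = 0
        leave_phase(pop, mild_env, phi=2.0, rng=rng)
        assert np.all(pop.status == FEEDING)

    def test_certain_departure_with_zero_k_orthogonalish_rail(self, rng):
        env = Environment.from_ratios([0.01])  # nearly flat rail
        pop = fresh_pop(n=20, k=0.0)
        pop.status[:] = FEEDING
        pop.food[:] = 0
        pop.x[:] = 499.9  # ideal rail nearly vertical: |delta alpha| ~ pi/2
        leave_phase(pop, env, phi=2.0, rng=rng)
        assert np.all(pop.status == SEARCHING)

    def test_empirical_leave_fraction_matches_probability(self, mild_env):
        """Observed departures match the mean P_leave within 3 sigma of
        binomial error over 10^4 agent-ticks."""
        rng = np.random.default_rng(3)
        n, reps = 100, 100
        k = 0.4
        p_expected = None
        left = 0
        for _ in range(reps):
            pop = fresh_pop(n=n, k=k)
            pop.status[:] = FEEDING
            pop.food[:] = 0  # V = 0.5 rail from the origin
            if p_expected is None:
                rail = mild_env.foods[0].rail_angle
                ideal = math.pi / 4
                a = 500 * math.sqrt(2) * math.cos(ideal - rail)
                p_expected = leave_probability(k, rail, ideal, a, 2.0)
            leave_phase(pop, mild_env, phi=2.0, rng=rng)
            left += int((pop.status == SEARCHING).sum())
        total = n * reps
        sigma = math.sqrt(total * p_expected * (1 - p_expected))
        assert abs(left - total * p_expected) < 3 * sigma


class TestRunGeneration:
    def test_zero_iterations_is_a_no_op(self, mild_env, rng):
        pop = fresh_pop(n=10)
        res = run_generation(pop, mild_env, competition(0.0, n_ind=10), n_iterations=0, rng=rng)
        assert res.fitness == pytest.approx(np.exp(-2.0))
        assert res.contests_involved.sum() == 0
        assert np.all(np.isnan(res.mean_beta_deg))

    def test_free_access_lets_everyone_breed(self, mild_env, rng):
        """With c = 0 and K = 1 every individual reaches F > 0.5 well within
        a 500-iteration generation (the balanced path is ~354 steps)."""
        pop = fresh_pop(n=50)
        res = run_generation(pop, mild_env, competition(0.0, n_ind=50), rng=rng)
        assert np.all(res.fitness > 0.5)
        assert res.contests_involved.sum() == 0

    def test_status_conservation_every_iteration(self, mild_env):
        """(feeding) + (displaced) + (searching) = n after every phase of
        every iteration."""
        rng = np.random.default_rng(5)
        pop = fresh_pop(n=60)
        cfg = competition(0.767, n_ind=60)
        for _ in range(40):
            for phase in (choose_food_phase, eat_phase, fitness_phase, leave_phase):
                if phase is choose_food_phase:
                    phase(pop, mild_env, cfg, rng)
                elif phase is fitness_phase:
                    phase(pop, mild_env, 2.0, rng)
                else:
                    phase(pop, mild_env, 2.0, rng)
                counts = np.bincount(pop.status, minlength=3)
                assert counts.sum() == 60

    def test_fitness_non_decreasing_through_eating(self, mild_env):
        """Movement is always toward the IT, so fitness never drops across
        an eat event."""
        rng = np.random.default_rng(8)
        pop = fresh_pop(n=30, k=0.5)
        cfg = competition(0.5, n_ind=30)
        for _ in range(200):
            choose_food_phase(pop, mild_env, cfg, rng)
            before = pop.fit.copy()
            eat_phase(pop, mild_env, 2.0, rng)
            fitness_phase(pop, mild_env, 2.0, rng)
            assert np.all(pop.fit >= before - 1e-12)
            leave_phase(pop, mild_env, 2.0, rng)
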