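import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from velopace import (
    CornerSpec,
    Course,
    Environment,
    GAParams,
    Rider,
    Segment,
    Strategy,
    ValidationError,
    brute_force_optimum,
    constant_power_baseline,
    evaluate,
    optimize,
    simulate,
    speed_bounds,
)
from velopace.optimizer import (
    compute_bounds,
    init_population,
    linear_recombination,
    real_mutation,
    select,
)


class ScriptedRng:
    """Minimal stand-in for numpy Generator with scripted draws."""

    def __init__(self, uniforms=None, integers=None, randoms=None, normals=None):
        self._uniform = uniforms
        self._integers = integers
        self._random = randoms
        self._normal = normals

    def uniform(self, lo, hi, size=None):
        return np.full(size, self._uniform) if self._uniform is not None else np.zeros(size)

    def integers(self, lo, hi, size=None):
        return np.array(self._integers.pop(0))

    def random(self, size=None):
        return np.full(size, self._random if self._random is not None else 0.0)

    def normal(self, loc, scale, size=None):
        return np.full(size, self._normal if self._normal is not None else 0.0)


small_ga = GAParams(population_size=60, max_generations=40, seed=1)


class TestEvaluate:
    def test_feasible_equals_time(self, rider, env, toy3_course):
        strat = Strategy(np.array([11.0, 10.0, 11.0]))
        res = simulate(strat, toy3_course, rider, env)
        assert res.within_budget
        assert evaluate(strat, toy3_course, rider, env) == pytest.approx(res.total_time)

    def test_overspend_penalty_arithmetic(self, rider, env, toy3_course):
        strat = Strategy(np.array([15.0, 13.0, 15.0]))
        res = simulate(strat, toy3_course, rider, env)
        tight = dataclasses.replace(rider, energy_budget=res.total_work - 1000.0)
        obj = evaluate(strat, toy3_course, tight, env, penalty_weight=0.01)
        assert obj == pytest.approx(res.total_time + 10.0)

    def test_deterministic(self, rider, env, toy3_course):
        strat = Strategy(np.array([12.0, 10.0, 12.0]))
        assert evaluate(strat, toy3_course, rider, env) == evaluate(
            strat, toy3_course, rider, env
        )

    def test_box_penalty(self, rider, env, toy3_course):
        bounds = speed_bounds(toy3_course, rider, env)
        over = Strategy(bounds[1] + 1.0)
        base = evaluate(over, toy3_course, rider, env)
        with_box = evaluate(over, toy3_course, rider, env, bounds=bounds, box_penalty_weight=10.0)
        assert with_box == pytest.approx(base + 30.0)


class TestInitPopulation:
    def test_seeded_determinism(self):
        bounds = (np.array([5.0, 6.0]), np.array([15.0, 16.0]))
        a = init_population(bounds, 5, np.random.default_rng(9))
        b = init_population(bounds, 5, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_degenerate_bounds_collapse(self):
        bounds = (np.array([7.0, 8.0]), np.array([7.0, 8.0]))
        pop = init_population(bounds, 4, np.random.default_rng(0))
        assert np.all(pop == np.array([7.0, 8.0]))

    def test_baseline_injected(self):
        bounds = (np.array([5.0]), np.array([15.0]))
        pop = init_population(bounds, 6, np.random.default_rng(0), baseline=np.array([9.5]))
        assert pop[0, 0] == 9.5

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            init_population((np.array([10.0]), np.array([5.0])), 4, np.random.default_rng(0))

    def test_within_bounds(self):
        bounds = (np.array([5.0, 6.0]), np.array([15.0, 16.0]))
        pop = init_population(bounds, 50, np.random.default_rng(3))
        assert np.all(pop >= bounds[0]) and np.all(pop <= bounds[1])


class TestLinearRecombination:
    bounds = (np.zeros(3), np.full(3, 100.0))

    def test_beta_zero_returns_parent_a(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        c0, _ = linear_recombination(a, b, ScriptedRng(uniforms=0.0), self.bounds)
        assert np.array_equal(c0, a)

    def test_beta_one_returns_parent_b(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        c0, _ = linear_recombination(a, b, ScriptedRng(uniforms=1.0), self.bounds)
        assert np.array_equal(c0, b)

    def test_identical_parents_identical_offspring(self, rng):
        a = np.array([3.0, 4.0, 5.0])
        c0, c1 = linear_recombination(a, a.copy(), rng, self.bounds)
        assert np.array_equal(c0, a) and np.array_equal(c1, a)

    def test_offspring_clipped(self, rng):
        bounds = (np.array([9.0, 9.0]), np.array([11.0, 11.0]))
        for _ in range(100):
            c0, c1 = linear_recombination(
                np.array([9.0, 11.0]), np.array([11.0, 9.0]), rng, bounds
            )
            for c in (c0, c1):
                assert np.all(c >= bounds[0]) and np.all(c <= bounds[1])

    def test_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            linear_recombination(np.zeros(2), np.zeros(3), rng, self.bounds)


class TestRealMutation:
    bounds = (np.zeros(4), np.full(4, 20.0))

    def test_pm_zero_identity(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(real_mutation(x, 0.0, rng, self.bounds), x)

    def test_zero_scale_identity(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.array_equal(real_mutation(x, 1.0, rng, self.bounds, scale=0.0), x)

    def test_always_within_bounds(self, rng):
        x = np.array([0.5, 10.0, 19.5, 20.0])
        for _ in range(10_000 // 4):
            y = real_mutation(x, 1.0, rng, self.bounds, scale=0.5)
            assert np.all(y >= self.bounds[0]) and np.all(y <= self.bounds[1])

    def test_does_not_modify_input(self, rng):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        real_mutation(x, 1.0, rng, self.bounds)
        assert np.array_equal(x, np.array([1.0, 2.0, 3.0, 4.0]))


class TestSelect:
    def test_population_of_one(self):
        pop = np.array([[5.0]])
        out = select(pop, np.array([1.0]), 4, np.random.default_rng(0))
        assert np.all(out == 5.0)

    def test_lower_objective_wins_tournament(self):
        pop = np.array([[1.0], [2.0]])
        rng = ScriptedRng(integers=[[0, 1], [1, 0]])
        out = select(pop, np.array([0.5, 9.9]), 2, rng)
        assert np.all(out == 1.0)  # best individual wins both orderings

    def test_seeded_determinism(self):
        pop = np.arange(10.0).reshape(-1, 1)
        obj = np.arange(10.0)
        a = select(pop, obj, 20, np.random.default_rng(4))
        b = select(pop, obj, 20, np.random.default_rng(4))
        assert np.array_equal(a, b)

    def test_mismatched_lengths(self):
        with pytest.raises(ValidationError):
            select(np.zeros((3, 1)), np.zeros(2), 2, np.random.default_rng(0))


class TestOptimize:
    def test_single_segment_budget_limited_closed_form(self, toy_rider, toy_env, flat_course):
        rider = dataclasses.replace(toy_rider, energy_budget=3000.0)

        # independent oracle: solve W(v) = (0.2 v^3 + 3 v - 230)(1000/v) = 3000
        def overspend(v):
            return (0.2 * v**3 + 3 * v - 230.0) * (1000.0 / v) - 3000.0

        v_star = brentq(overspend, 10.0, 20.83)
        result = optimize(flat_course, rider, toy_env, small_ga)
        assert result.feasible
        assert result.best_strategy.speeds[0] == pytest.approx(v_star, rel=1e-3)
        assert result.best_time == pytest.approx(1000.0 / v_star, rel=1e-3)

    def test_single_segment_cap_when_affordable(self, toy_rider, toy_env, flat_course):
        rider = dataclasses.replace(toy_rider, energy_budget=1e6)
        result = optimize(flat_course, rider, toy_env, small_ga)
        assert result.best_strategy.speeds[0] == pytest.approx(rider.v_max_flat, rel=1e-6)

    def test_zero_budget_gives_recovery_strategy(self, rider, env):
        course = Course((Segment(800.0), Segment(1200.0)))
        rider0 = dataclasses.replace(rider, energy_budget=0.0)
        result = optimize(course, rider0, env, small_ga)
        lower, _ = speed_bounds(course, rider0, env)
        assert result.feasible
        assert result.best_strategy.speeds == pytest.approx(lower, abs=1e-9)
        assert result.best_time == pytest.approx(
            simulate(Strategy(lower), course, rider0, env).total_time
        )

    def test_ga_never_loses_to_injected_baseline(self, rider, env, toy3_course):
        base = constant_power_baseline(toy3_course, rider, env)
        base_time = simulate(base.strategy, toy3_course, rider, env).total_time
        result = optimize(toy3_course, rider, env, small_ga)
        assert result.best_time <= base_time + 1e-9

    def test_budget_feasibility(self, rider, env, toy3_course):
        result = optimize(toy3_course, rider, env, small_ga)
        assert result.best_work <= rider.energy_budget + 1.0

    def test_history_monotone_nonincreasing(self, rider, env, toy3_course):
        result = optimize(toy3_course, rider, env, small_ga)
        assert np.all(np.diff(result.history) <= 0)
        assert len(result.history) <= small_ga.max_generations

    def test_reproducible(self, rider, env, toy3_course):
        a = optimize(toy3_course, rider, env, small_ga)
        b = optimize(toy3_course, rider, env, small_ga)
        assert np.array_equal(a.best_strategy.speeds, b.best_strategy.speeds)
        assert np.array_equal(a.history, b.history)
        assert a.best_time == b.best_time
        assert a.n_evaluations == b.n_evaluations

    def test_light_oracle_equivalence(self, rider, env):
        course = Course((Segment(1000.0), Segment(600.0, grade_angle=math.atan(0.04))))
        oracle_time = simulate(
            brute_force_optimum(course, rider, env, 13), course, rider, env
        ).total_time
        for seed in (0, 1):
            result = optimize(
                course, rider, env, dataclasses.replace(small_ga, seed=seed)
            )
            assert abs(result.best_time - oracle_time) <= 0.01 * oracle_time

    def test_infeasible_bounds_name_segment(self, rider, env):
        # tight hairpin on a climb: corner cap below the recovery speed
        seg = Segment(50.0, grade_angle=math.atan(0.01), corner=CornerSpec(0.5))
        with pytest.raises(ValidationError, match="segment"):
            optimize(Course((Segment(500.0), seg)), rider, env, small_ga)

    def test_stagnation_termination(self, rider, env, flat_course):
        ga = GAParams(
            population_size=40, max_generations=200, seed=0, stagnation_patience=10
        )
        result = optimize(flat_course, rider, env, ga)
        assert result.termination in {"stagnation", "max_generations"}
        assert len(result.history) <= 200


class TestBruteForce:
    def test_one_segment_enumeration(self, toy_rider, toy_env, flat_course):
        rider = dataclasses.replace(toy_rider, energy_budget=3000.0)
        lower, upper = compute_bounds(flat_course, rider, toy_env)
        grid = np.linspace(lower[0], upper[0], 11)
        best = None
        for v in grid:
            res = simulate(Strategy(np.array([v])), flat_course, rider, toy_env)
            if res.total_work <= rider.energy_budget + 1e-3:
                if best is None or res.total_time < best[1]:
                    best = (v, res.total_time)
        oracle = brute_force_optimum(flat_course, rider, toy_env, 11)
        assert oracle.speeds[0] == pytest.approx(best[0])

    def test_oracle_beats_every_feasible_grid_point(self, rider, env, toy3_course):
        oracle = brute_force_optimum(toy3_course, rider, env, 7)
        t_star = simulate(oracle, toy3_course, rider, env).total_time
        lower, upper = compute_bounds(toy3_course, rider, env)
        rng = np.random.default_rng(0)
        for _ in range(50):
            idx = rng.integers(0, 7, size=3)
            speeds = np.array([np.linspace(lower[i], upper[i], 7)[idx[i]] for i in range(3)])
            res = simulate(Strategy(speeds), toy3_course, rider, env)
            if res.total_work <= rider.energy_budget + 1e-3:
                assert t_star <= res.total_time + 1e-9

    def test_guard_refuses_oversized_grid(self, rider, env):
        course = Course(tuple(Segment(100.0) for _ in range(9)))
        with pytest.raises(ValidationError, match="guard"):
            brute_force_optimum(course, rider, env, 11)

    def test_deterministic(self, rider, env, toy3_course):
        a = brute_force_optimum(toy3_course, rider, env, 9)
        b = brute_force_optimum(toy3_course, rider, env, 9)
        assert np.array_equal(a.speeds, b.speeds)
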