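import numpy as np
import pytest

from oracles import tail_index_loglog
from svmswarm import (
    OptimizerConfig,
    SearchBounds,
    cs_iteration,
    cs_local_walk,
    hybrid_cspso_iteration,
    init_state,
    levy_flight_step,
    levy_samples,
    optimize,
    pso_step,
)
from svmswarm.data import InvalidConfig, InvalidMethod, NonFiniteFitness


def sphere(x):
    """Maximized at the origin (value 0)."""
    return -float(np.sum(np.asarray(x) ** 2))


BOX = SearchBounds(lower=np.array([-5.0, -5.0]), upper=np.array([5.0, 5.0]))


class _OnesRng:
    """Stub generator whose uniform draws are all 1 (for hand examples)."""

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.ones(size) if size is not None else 1.0


class TestPsoStep:
    def test_hand_worked_velocity_update(self):
        # v=0.5, x=1, pbest=2, gbest=3, c1=1.3, c2=1.87, r1=r2=1
        # v' = 0.5 + 1.3*1*(2-1) + 1.87*1*(3-1) = 5.54 ; x' = 6.54
        bounds = SearchBounds(lower=np.array([0.0]), upper=np.array([100.0]))
        cfg = OptimizerConfig(population=1, c1=1.3, c2=1.87,
                              velocity_clamp_fraction=1.0)
        from svmswarm.optimizers import SwarmState

        state = SwarmState(
            positions=np.array([[1.0]]),
            velocities=np.array([[0.5]]),
            fitnesses=np.array([0.0]),
            pbest_positions=np.array([[2.0]]),
            pbest_fitnesses=np.array([1.0]),
            gbest_position=np.array([3.0]),
            gbest_fitness=2.0,
            bounds=bounds,
        )
        pso_step(state, cfg, lambda x: -1.0, _OnesRng())
        assert state.velocities[0, 0] == pytest.approx(5.54, abs=1e-12)
        assert state.positions[0, 0] == pytest.approx(6.54, abs=1e-12)

    def test_particle_at_shared_best_with_zero_velocity_stays_put(self, rng):
        from svmswarm.optimizers import SwarmState

        x = np.array([[1.5, -2.0]])
        state = SwarmState(
            positions=x.copy(),
            velocities=np.zeros((1, 2)),
            fitnesses=np.array([sphere(x[0])]),
            pbest_positions=x.copy(),
            pbest_fitnesses=np.array([sphere(x[0])]),
            gbest_position=x[0].copy(),
            gbest_fitness=sphere(x[0]),
            bounds=BOX,
        )
        pso_step(state, OptimizerConfig(population=1), sphere, rng)
        assert np.array_equal(state.positions, x)

    def test_zero_acceleration_is_pure_drift(self, rng):
        from svmswarm.optimizers import SwarmState

        x = np.array([[1.0, 1.0], [-2.0, 0.5]])
        v = np.array([[0.25, -0.5], [0.1, 0.2]])
        state = SwarmState(
            positions=x.copy(),
            velocities=v.copy(),
            fitnesses=np.array([sphere(r) for r in x]),
            pbest_positions=x.copy(),
            pbest_fitnesses=np.array([sphere(r) for r in x]),
            gbest_position=x[0].copy(),
            gbest_fitness=sphere(x[0]),
            bounds=BOX,
        )
        pso_step(state, OptimizerConfig(population=2, c1=0.0, c2=0.0), sphere, rng)
        assert state.positions == pytest.approx(x + v)


class TestLevy:
    def test_zero_alpha_leaves_position_unchanged(self, rng):
        cfg = OptimizerConfig(levy_alpha_scale=0.0)
        x = np.array([1.0, -3.0])
        assert np.array_equal(levy_flight_step(x, BOX, cfg, rng), x)

    def test_tail_index_recovered(self, rng):
        lam = 1.5
        L = levy_samples(100_000, lam, rng)
        assert tail_index_loglog(L) == pytest.approx(lam, abs=0.15)

    def test_steps_stay_finite_and_inside_bounds(self, rng):
        cfg = OptimizerConfig(levy_alpha_scale=0.1)
        X = rng.uniform(BOX.lower, BOX.upper, size=(200, 2))
        out = levy_flight_step(X, BOX, cfg, rng)
        assert np.all(np.isfinite(out))
        assert np.all(out >= BOX.lower) and np.all(out <= BOX.upper)


class TestLocalWalk:
    def test_pa_zero_is_identity(self, rng):
        X = rng.uniform(BOX.lower, BOX.upper, size=(10, 2))
        out = cs_local_walk(X, BOX, OptimizerConfig(pa=0.0), rng)
        assert np.array_equal(out, X)

    def test_pa_one_perturbs_every_coordinate(self, rng):
        X = rng.uniform(BOX.lower, BOX.upper, size=(12, 2))
        out = cs_local_walk(X, BOX, OptimizerConfig(pa=1.0), rng)
        assert np.all(out != X)

    def test_perturbation_frequency_matches_pa(self, rng):
        # 10^4 coordinate draws; expected changed fraction = pa
        cfg = OptimizerConfig(pa=0.262)
        changed = total = 0
        for _ in range(100):
            X = rng.uniform(BOX.lower, BOX.upper, size=(50, 2))
            out = cs_local_walk(X, BOX, cfg, rng)
            changed += int(np.sum(out != X))
            total += X.size
        assert changed / total == pytest.approx(0.262, abs=0.01)


class TestCsIteration:
    def test_constant_fitness_keeps_best_unchanged(self, rng):
        cfg = OptimizerConfig(population=8)
        state = init_state(BOX, cfg, lambda x: 1.0, rng)
        for _ in range(5):
            cs_iteration(state, cfg, lambda x: 1.0, rng)
        assert state.gbest_fitness == 1.0

    def test_greedy_acceptance_never_degrades_nests(self, rng):
        cfg = OptimizerConfig(population=10)
        state = init_state(BOX, cfg, sphere, rng)
        before = state.fitnesses.copy()
        cs_iteration(state, cfg, sphere, rng)
        assert np.all(state.fitnesses >= before)


class TestHybrid:
    def test_degenerate_hybrid_equals_pso_bitwise(self):
        cfg = dict(population=6, iterations=15, seed=99,
                   pa=0.0, levy_alpha_scale=0.0)
        r_pso = optimize("pso", sphere, BOX, OptimizerConfig(**cfg))
        r_hyb = optimize("cspso", sphere, BOX, OptimizerConfig(**cfg))
        assert r_pso.history == r_hyb.history
        assert np.array_equal(r_pso.best_position, r_hyb.best_position)

    def test_best_fitness_nondecreasing(self, rng):
        cfg = OptimizerConfig(population=8)
        state = init_state(BOX, cfg, sphere, rng)
        best = state.gbest_fitness
        for _ in range(10):
            hybrid_cspso_iteration(state, cfg, sphere, rng)
            assert state.gbest_fitness >= best
            best = state.gbest_fitness

    def test_sequential_strategy_runs(self):
        cfg = OptimizerConfig(population=6, iterations=10, seed=1,
                              hybrid_strategy="sequential")
        res = optimize("cspso", sphere, BOX, cfg)
        assert len(res.history) == 11
        assert res.best_fitness >= res.history[0]["best_fitness"]


class TestOptimize:
    def test_zero_iterations_returns_initial_best(self):
        cfg = OptimizerConfig(population=12, iterations=0, seed=4)
        res = optimize("pso", sphere, BOX, cfg)
        assert len(res.history) == 1
        rng = np.random.default_rng(4)
        X = rng.uniform(BOX.lower, BOX.upper, size=(12, 2))
        assert res.best_fitness == max(sphere(x) for x in X)

    @pytest.mark.parametrize("method", ["pso", "cs", "cspso"])
    def test_quadratic_1d_optimum_found(self, method):
        # maximize -(x-3)^2 on [0, 10]; optimum at x = 3
        bounds = SearchBounds(lower=np.array([0.0]), upper=np.array([10.0]))
        hits = 0
        for seed in range(20):
            cfg = OptimizerConfig(seed=seed)
            res = optimize(method, lambda x: -((x[0] - 3.0) ** 2), bounds, cfg)
            hits += abs(res.best_position[0] - 3.0) <= 0.01
        assert hits >= 19

    @pytest.mark.parametrize("method", ["pso", "cs", "cspso"])
    def test_seeded_determinism(self, method):
        cfg = OptimizerConfig(population=10, iterations=25, seed=7)
        r1 = optimize(method, sphere, BOX, cfg)
        r2 = optimize(method, sphere, BOX, cfg)
        assert r1.history == r2.history
        assert np.array_equal(r1.best_position, r2.best_position)

    @pytest.mark.parametrize("method", ["pso", "cs", "cspso"])
    def test_all_evaluated_positions_respect_bounds(self, method):
        seen = []

        def recording_sphere(x):
            seen.append(np.array(x))
            return sphere(x)

        cfg = OptimizerConfig(population=8, iterations=15, seed=3)
        optimize(method, recording_sphere, BOX, cfg)
        S = np.vstack(seen)
        assert np.all(S >= BOX.lower) and np.all(S <= BOX.upper)

    @pytest.mark.parametrize("method", ["pso", "cs", "cspso"])
    def test_elitism_on_random_objective(self, method, rng):
        # fitness is a hash-like arbitrary deterministic function
        def messy(x):
            return float(np.sin(13.7 * x[0]) * np.cos(7.1 * x[1]) + 0.01 * x[0])

        cfg = OptimizerConfig(population=8, iterations=30, seed=11)
        res = optimize(method, messy, BOX, cfg)
        best = [h["best_fitness"] for h in res.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_invalid_method_rejected(self):
        with pytest.raises(InvalidMethod):
            optimize("annealing", sphere, BOX, OptimizerConfig())

    def test_non_finite_fitness_raises(self):
        with pytest.raises(NonFiniteFitness):
            optimize("pso", lambda x: float("nan"), BOX,
                     OptimizerConfig(population=4, iterations=1))


def test_config_validation():
    with pytest.raises(InvalidConfig):
        OptimizerConfig(pa=1.5)
    with pytest.raises(InvalidConfig):
        OptimizerConfig(levy_lambda=2.5)
    with pytest.raises(InvalidConfig):
        OptimizerConfig(population=0)
    with pytest.raises(InvalidConfig):
        SearchBounds(lower=np.array([1.0]), upper=np.array([1.0]))


def test_table_defaults():
    cfg = OptimizerConfig()
    assert (cfg.population, cfg.iterations) == (18, 120)
    assert (cfg.c1, cfg.c2, cfg.pa) == (1.3, 1.87, 0.262)
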