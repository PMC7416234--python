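"""Binary PSO tests: updates, transfer function, fitness, full runs."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from mipso import (
    FeatureMatrix,
    PSOConfig,
    inertia_weight,
    initialize_swarm,
    mse_inverse_fitness,
    run_pso,
    update_position_binary,
    update_velocity,
)


@pytest.fixture
def defaults():
    return PSOConfig(seed=0)


class TestConfigAndInertia:
    def test_defaults_match_tuned_operating_point(self, defaults):
        assert (defaults.n_particles, defaults.n_iterations) == (100, 100)
        assert (defaults.c1, defaults.c2) == (1.5, 1.5)
        assert (defaults.w_max, defaults.w_min, defaults.v_max) == (0.8, 0.4, 20.0)

    def test_linear_inertia_schedule(self, defaults):
        assert inertia_weight(0, defaults) == pytest.approx(0.8)
        assert inertia_weight(100, defaults) == pytest.approx(0.4)
        assert inertia_weight(50, defaults) == pytest.approx(0.6)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PSOConfig(n_particles=1)
        with pytest.raises(ValueError):
            PSOConfig(w_max=0.3, w_min=0.4)
        with pytest.raises(ValueError):
            PSOConfig(v_max=0.0)


class TestSwarm:
    def test_initialisation_shape_and_reproducibility(self, defaults):
        s1 = initialize_swarm(2240, defaults, rng=np.random.default_rng(9))
        assert s1.positions.shape == (100, 2240)
        assert set(np.unique(s1.positions)) <= {0, 1}
        assert np.all(np.abs(s1.velocities) <= defaults.v_max)
        s2 = initialize_swarm(2240, defaults, rng=np.random.default_rng(9))
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.velocities, s2.velocities)

    def test_gbest_is_argmax_of_initial_fitness(self):
        cfg = PSOConfig(n_particles=2, n_iterations=1, seed=3)
        state = initialize_swarm(1, cfg, fitness=lambda m: float(m.sum()), rng=np.random.default_rng(3))
        assert state.gbest_fitness == max(state.pbest_fitness)

    def test_rejects_dimension_below_one(self, defaults):
        with pytest.raises(ValueError):
            initialize_swarm(0, defaults)

    def test_stagnation_keeps_zero_velocity(self):
        cfg = PSOConfig(n_particles=4, n_iterations=10, seed=0)
        state = initialize_swarm(6, cfg, rng=np.random.default_rng(0))
        state.velocities[:] = 0.0
        state.pbest_positions = state.positions.copy()
        state.gbest_position = state.positions[0].copy()
        state.positions = np.tile(state.gbest_position, (4, 1))
        state.pbest_positions = state.positions.copy()
        update_velocity(state, cfg, np.random.default_rng(1), t=0)
        assert np.all(state.velocities == 0)

    def test_velocity_persistence_without_attraction(self):
        cfg = PSOConfig(n_particles=3, n_iterations=10, c1=1e-12, c2=1e-12, w_max=1.0, w_min=1.0, seed=0)
        state = initialize_swarm(5, cfg, rng=np.random.default_rng(2))
        v0 = state.velocities.copy()
        update_velocity(state, cfg, np.random.default_rng(3), t=0)
        np.testing.assert_allclose(state.velocities, v0, atol=1e-10)

    def test_velocity_always_clamped(self, defaults):
        state = initialize_swarm(50, defaults, rng=np.random.default_rng(4))
        state.velocities[:] = 19.9
        for t in range(5):
            update_velocity(state, defaults, np.random.default_rng(t), t=t)
            update_position_binary(state, np.random.default_rng(100 + t))
            assert np.max(np.abs(state.velocities)) <= 20.0


class TestSigmoidTransfer:
    @pytest.mark.parametrize(
        "v,expected,tol",
        [(0.0, 0.5, 0.01), (1.0, expit(1.0), 0.01), (20.0, 1.0, 0.001)],
    )
    def test_bit_probability_follows_sigmoid(self, v, expected, tol):
        cfg = PSOConfig(n_particles=100, n_iterations=1, seed=0)
        state = initialize_swarm(1000, cfg, rng=np.random.default_rng(0))
        state.velocities[:] = v
        update_position_binary(state, np.random.default_rng(12345))
        freq = state.positions.mean()  # 1e5 draws
        assert freq == pytest.approx(expected, abs=tol)

    def test_chi_square_goodness_of_fit(self):
        v = 1.5
        cfg = PSOConfig(n_particles=100, n_iterations=1, seed=0)
        state = initialize_swarm(100, cfg, rng=np.random.default_rng(1))
        state.velocities[:] = v
        update_position_binary(state, np.random.default_rng(777))
        ones = int(state.positions.sum())
        n = state.positions.size
        p = expit(v)
        _, pval = stats.chisquare([ones, n - ones], [n * p, n * (1 - p)])
        assert pval > 1e-3


class TestFitness:
    @staticmethod
    def _features(labels):
        labels = np.asarray(labels)
        vals = np.column_stack([labels * 1.0, np.ones_like(labels, dtype=float)])
        return FeatureMatrix(vals, [(0, 1.0), (0, 2.0)], labels)

    def test_perfect_prediction_hits_the_cap(self):
        rng = np.random.default_rng(0)
        y = np.resize([1, 1, -1, -1], 20)
        train = self._features(y)
        fit = mse_inverse_fitness(np.array([True, False]), train, train)
        assert fit == pytest.approx(1e12)

    def test_error_counts_map_to_inverse_squared_error(self):
        """k wrong +-1 labels give fitness ~ 1/(4k): 0.25, 0.125, ..."""
        y_train = np.resize([1, -1], 40)
        train = self._features(y_train)
        for k in (1, 2, 5):
            y_eval = np.resize([1, -1], 20)
            flipped = y_eval.copy()
            flipped[:k] *= -1
            eval_fm = self._features(y_eval)
            eval_fm.labels = flipped  # truth disagrees with the feature sign k times
            fit = mse_inverse_fitness(np.array([True, False]), train, eval_fm)
            assert fit == pytest.approx(1.0 / (4 * k), rel=1e-9)

    def test_empty_mask_is_worst_possible(self):
        train = self._features(np.resize([1, -1], 10))
        assert mse_inverse_fitness(np.array([False, False]), train, train) == -np.inf

    def test_degenerate_training_split_is_worst_possible(self):
        y = np.resize([1, -1], 10)
        train = self._features(y)
        train.labels = np.ones(10, dtype=np.int64)  # single class
        eval_fm = self._features(y)
        assert mse_inverse_fitness(np.array([True, True]), train, eval_fm) == -np.inf


class TestRunPso:
    def test_onemax_reaches_the_optimum(self):
        cfg = PSOConfig(seed=0)
        hits = sum(
            run_pso(10, cfg, lambda m: float(m.sum()), rng=np.random.default_rng(s)).mask.sum() == 10
            for s in range(5)
        )
        assert hits == 5

    def test_planted_mask_recovered(self):
        hidden = np.arange(15) % 3 == 0
        cfg = PSOConfig(seed=0)
        res = run_pso(
            15,
            cfg,
            lambda m: float(15 - np.sum(m != hidden)),
            rng=np.random.default_rng(1),
        )
        assert np.array_equal(res.mask.astype(bool), hidden)

    def test_constant_fitness_keeps_best_initial_particle(self):
        cfg = PSOConfig(n_particles=20, n_iterations=10, seed=5)
        res = run_pso(12, cfg, lambda m: 1.0, rng=np.random.default_rng(5))
        assert np.all(res.trace == 1.0)

    def test_gbest_trace_monotone_nondecreasing(self):
        cfg = PSOConfig(n_particles=20, n_iterations=30, seed=2)
        rng_f = np.random.default_rng(0)
        weights = rng_f.random(25)
        res = run_pso(25, cfg, lambda m: float(weights[m].sum()), rng=np.random.default_rng(2))
        assert np.all(np.diff(res.trace) >= 0)
        assert len(res.trace) == cfg.n_iterations + 1

    def test_full_trajectory_reproducible(self):
        cfg = PSOConfig(n_particles=15, n_iterations=20, seed=8)
        f = lambda m: float(m.sum() % 7)
        r1 = run_pso(18, cfg, f, rng=np.random.default_rng(8))
        r2 = run_pso(18, cfg, f, rng=np.random.default_rng(8))
        assert np.array_equal(r1.mask, r2.mask)
        assert np.array_equal(r1.trace, r2.trace)

    def test_nan_fitness_aborts(self):
        cfg = PSOConfig(n_particles=5, n_iterations=2, seed=0)
        with pytest.raises(ValueError, match="NaN"):
            run_pso(4, cfg, lambda m: np.nan, rng=np.random.default_rng(0))
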