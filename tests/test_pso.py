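"""Binary particle-swarm selection: velocity/transfer/binarisation rules,
wrapper fitness, and swarm behaviour."""

import numpy as np
import pytest

from histofuse import PSOSelector, make_feature_table, pso_select, wrapper_fitness
from histofuse.pso import (
    SelectionResult,
    SwarmState,
    binarize_position,
    transfer_sigmoid,
    update_velocity,
)


def make_state(P=3, d=4, inertia=1.0, a1=0.0, a2=0.0, seed=0):
    rng = np.random.default_rng(seed)
    pos = (rng.random((P, d)) < 0.5).astype(float)
    pos[pos.sum(axis=1) == 0, 0] = 1.0
    return SwarmState(positions=pos, velocities=rng.standard_normal((P, d)),
                      pbest_positions=pos.copy(), pbest_fitness=np.zeros(P),
                      gbest_position=pos[0].copy(), gbest_fitness=0.0,
                      inertia=inertia, a1=a1, a2=a2, rng=rng)


class TestVelocityUpdate:
    def test_degenerate_coefficients_keep_velocity(self):
        s = make_state(a1=0.0, a2=0.0, inertia=1.0)
        v0 = s.velocities.copy()
        update_velocity(s)
        assert np.allclose(s.velocities, v0)

    def test_half_inertia_halves_velocity_at_consensus(self):
        s = make_state(inertia=0.5, a1=2.0, a2=2.0)
        s.pbest_positions = s.positions.copy()
        s.gbest_position = s.positions[0].copy()
        s.positions = np.tile(s.gbest_position, (3, 1))
        s.pbest_positions = s.positions.copy()
        v0 = s.velocities.copy()
        update_velocity(s)
        assert np.allclose(s.velocities, 0.5 * v0)

    def test_analytic_single_component(self):
        s = make_state(P=2, d=1, inertia=0.0, a1=1.0, a2=0.0)
        s.positions = np.zeros((2, 1))
        s.pbest_positions = np.ones((2, 1))
        update_velocity(s, rm1=np.ones((2, 1)), rm2=np.zeros((2, 1)))
        assert np.allclose(s.velocities, 1.0)

    def test_clamped_to_v_max(self):
        s = make_state(inertia=10.0)
        s.velocities[:] = 5.0
        update_velocity(s, v_max=6.0)
        assert s.velocities.max() <= 6.0


class TestTransferAndBinarise:
    def test_sigmoid_values(self):
        assert transfer_sigmoid(0.0) == pytest.approx(0.5)
        assert transfer_sigmoid(np.log(3)) == pytest.approx(0.75)
        assert transfer_sigmoid(-60.0) == pytest.approx(0.0, abs=1e-12)

    def test_threshold_rule(self):
        assert binarize_position(np.array([0.9]), np.array([0.5]))[0] == 1
        assert binarize_position(np.array([0.1]), np.array([0.5]))[0] == 0
        draws = np.random.default_rng(0).random(20)
        assert (binarize_position(np.ones(20), draws) == 1).all()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binarize_position(np.ones(3), np.ones(4))


class TestWrapperFitness:
    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(0)
        X = np.zeros((60, 3)) + rng.normal(0, 1e-9, (60, 3))
        y = np.arange(60) % 2
        f = wrapper_fitness(X, y, np.ones(3, bool), penalty=0.0)
        assert 0.2 <= f <= 0.8

    def test_planted_mask_beats_noise_mask(self):
        wins = 0
        for seed in range(10):
            t = make_feature_table(120, 20, 5, 2.0, 4, seed=seed)
            planted = np.zeros(20, bool)
            planted[sorted(t.informative_indices)] = True
            noise = ~planted
            fp = wrapper_fitness(t.matrix, t.labels, planted, seed=seed)
            fn = wrapper_fitness(t.matrix, t.labels, noise, seed=seed)
            wins += fp > fn
        assert wins == 10

    def test_zero_penalty_ignores_mask_size(self, planted_table):
        X, y = planted_table.matrix, planted_table.labels
        m_small = np.zeros(60, bool)
        m_small[:5] = True
        f1 = wrapper_fitness(X, y, m_small, penalty=0.0)
        # fitness difference between penalised and unpenalised runs is
        # exactly the penalty term
        f2 = wrapper_fitness(X, y, m_small, penalty=0.01)
        assert f1 - f2 == pytest.approx(0.01 * m_small.mean())

    def test_empty_mask_rejected(self, planted_table):
        with pytest.raises(ValueError):
            wrapper_fitness(planted_table.matrix, planted_table.labels,
                            np.zeros(60, bool))


class TestSwarmRun:
    def test_single_iteration_returns_best_initial_particle(self):
        t = make_feature_table(40, 2, 1, 2.0, 2, seed=0)
        res = pso_select(t.matrix, t.labels, n_particles=2, n_iter=1, seed=0)
        assert res.fitness_trace.size == 1
        assert res.n_selected >= 1

    def test_gbest_trace_monotone_nondecreasing(self):
        for seed in range(3):
            t = make_feature_table(60, 15, 4, 1.5, 3, seed=seed)
            res = pso_select(t.matrix, t.labels, n_particles=6, n_iter=8,
                             seed=seed)
            assert (np.diff(res.fitness_trace) >= 0).all()

    def test_deterministic_per_seed(self, planted_table):
        X, y = planted_table.matrix, planted_table.labels
        a = pso_select(X, y, n_particles=5, n_iter=4, seed=7)
        b = pso_select(X, y, n_particles=5, n_iter=4, seed=7)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.fitness_trace, b.fitness_trace)

    def test_frozen_swarm_never_moves(self, planted_table):
        # a1 = a2 = 0 with zero initial velocities: no preference signal,
        # positions must stay at their initialisation
        X, y = planted_table.matrix, planted_table.labels
        res = pso_select(X, y, n_particles=4, n_iter=3, a1=0.0, a2=0.0, seed=1)
        rng = np.random.default_rng(1)
        init = (rng.random((4, 60)) < 0.5).astype(float)
        best = max(
            range(4),
            key=lambda p: wrapper_fitness(X, y, init[p] > 0.5, seed=1))
        assert np.array_equal(res.mask, init[best] > 0.5)

    def test_selector_estimator_interface(self, planted_table):
        X, y = planted_table.matrix, planted_table.labels
        sel = PSOSelector(n_particles=5, n_iter=3, random_state=0).fit(X, y)
        Xt = sel.transform(X)
        assert Xt.shape == (200, sel.result_.n_selected)
        assert np.array_equal(sel.get_support(), sel.result_.mask)

    def test_result_requires_nonempty_mask(self):
        with pytest.raises(ValueError):
            SelectionResult(mask=np.zeros(4, bool), scores=np.zeros(4),
                            method="pso", seed=0)
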