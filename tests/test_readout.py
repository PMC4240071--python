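"""Perceptron readout: algebra, learning rule, closed-loop protocol."""

import numpy as np
import pytest

from striatal_lsm.circuit import ScaleFactors, build_circuit
from striatal_lsm.readout import (
    ReadoutSession,
    TrainingSchedule,
    action_to_move,
    advocate,
    perceptron_update,
    train,
)
from striatal_lsm.tasks import make_task


@pytest.fixture(scope="module")
def tiny_circuit():
    return build_circuit(n_msn=60, n_fsi=6, n_cortex=50, seed=21,
                         scale=ScaleFactors(18, 113))


class TestAdvocate:
    def test_zero_weights_zero_action(self):
        assert np.all(advocate(np.zeros((4, 10)), np.ones(10)) == 0.0)

    def test_single_weight(self):
        W = np.zeros((4, 5))
        W[0, 3] = 2.5
        s = np.zeros(5)
        s[3] = 1.2
        np.testing.assert_allclose(advocate(W, s), [3.0, 0, 0, 0])

    def test_linearity(self, rng):
        W = rng.normal(size=(4, 8))
        s1, s2 = rng.normal(size=8), rng.normal(size=8)
        np.testing.assert_allclose(
            advocate(W, s1 + s2), advocate(W, s1) + advocate(W, s2)
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            advocate(np.zeros((4, 5)), np.zeros(6))


class TestPerceptronUpdate:
    def test_aligned_action_zero_update(self, rng):
        r = np.array([1.0, 0, 0, 0])
        a = np.array([3.0, 0, 0, 0])  # same direction
        s = rng.random((50, 8))
        dW = perceptron_update(np.zeros((4, 8)), r, a, s, 0.01)
        np.testing.assert_allclose(dW, 0.0, atol=1e-15)

    def test_zero_samples_zero_update(self):
        dW = perceptron_update(np.zeros((4, 8)), np.array([1.0, 0, 0, 0]),
                               np.array([0.0, 1, 0, 0]), np.zeros((50, 8)), 0.01)
        np.testing.assert_array_equal(dW, 0.0)

    def test_single_sample_hand_computation(self):
        # unit state at neuron j, r = East, a = West:
        # err = (1,0,0,0) - (0,1,0,0); dW[:, j] = lr * err
        s = np.zeros((1, 5))
        s[0, 2] = 1.0
        dW = perceptron_update(np.zeros((4, 5)), np.array([1.0, 0, 0, 0]),
                               np.array([0.0, 1.0, 0, 0]), s, 0.5)
        expect = np.zeros((4, 5))
        expect[0, 2] = 0.5
        expect[1, 2] = -0.5
        np.testing.assert_allclose(dW, expect)

    def test_accumulates_over_samples(self, rng):
        r = np.array([0.0, 0, 1.0, 0])
        a = np.array([1.0, 0, 0, 0])
        s = rng.random((50, 6))
        dW = perceptron_update(np.zeros((4, 6)), r, a, s, 0.1)
        single = sum(
            perceptron_update(np.zeros((4, 6)), r, a, s[k:k + 1], 0.1)
            for k in range(50)
        )
        np.testing.assert_allclose(dW, single, rtol=1e-10)

    def test_separable_patterns_learned(self, rng):
        """Two fixed disjoint liquid patterns mapped to E and W reach zero
        training error within 100 steps (perceptron convergence)."""
        sE = np.zeros(20)
        sE[:10] = rng.random(10) + 0.5
        sW = np.zeros(20)
        sW[10:] = rng.random(10) + 0.5
        rE = np.array([1.0, 0, 0, 0])
        rW = np.array([0.0, 1.0, 0, 0])
        W = np.zeros((4, 20))
        for step in range(100):
            s, r = (sE, rE) if step % 2 == 0 else (sW, rW)
            a = advocate(W, s)
            W = W + perceptron_update(W, r, a, s[None, :], 0.1)
        aE, aW = advocate(W, sE), advocate(W, sW)
        assert aE.argmax() == 0 and aW.argmax() == 1
        err = np.linalg.norm(rE - aE / np.linalg.norm(aE)) + np.linalg.norm(
            rW - aW / np.linalg.norm(aW))
        assert err < 0.2


class TestActionToMove:
    def test_pure_east(self):
        np.testing.assert_allclose(
            action_to_move(np.array([1.0, 0, 0, 0]), 0.02), [0.02, 0.0]
        )

    def test_cancellation_no_move(self):
        np.testing.assert_array_equal(
            action_to_move(np.array([1.0, 1, 1, 1]), 0.02), [0.0, 0.0]
        )

    def test_step_size_norm(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            move = action_to_move(a, 0.05)
            if np.linalg.norm(move) > 0:
                assert np.linalg.norm(move) == pytest.approx(0.05)


class TestTrainingLoop:
    def test_zero_learning_rate_leaves_weights(self, tiny_circuit):
        sched = TrainingSchedule(n_train=3, n_test=1, learning_rate=0.0)
        session = ReadoutSession(tiny_circuit, make_task("GOAL"), sched, seed=1)
        session.train(3)
        assert np.all(session.weights == 0.0)

    def test_identical_seeds_identical_weights(self, tiny_circuit):
        results = []
        for _ in range(2):
            sched = TrainingSchedule(n_train=5, n_test=1)
            session = ReadoutSession(tiny_circuit, make_task("MG5"), sched, seed=4)
            results.append(session.train(5).copy())
        np.testing.assert_array_equal(results[0], results[1])

    def test_training_never_touches_circuit(self, tiny_circuit):
        sched = TrainingSchedule(n_train=3, n_test=1)
        session = ReadoutSession(tiny_circuit, make_task("GOAL"), sched, seed=2)
        before = session.net.weight.copy()
        session.train(3)
        np.testing.assert_array_equal(session.net.weight, before)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            TrainingSchedule(step_duration=50.0, read_latency=50.0, learn_samples=50)

    def test_performance_bounds_and_baseline(self, tiny_circuit):
        """Untrained performance is exactly 1 (zero action against unit
        targets); everything stays within [0, 2]."""
        sched = TrainingSchedule(n_train=0, n_test=4, learning_rate=0.0)
        session = ReadoutSession(tiny_circuit, make_task("MG5"), sched, seed=3)
        perf, gen = session.evaluate(4, measure_generalization=True)
        assert perf == pytest.approx(1.0)
        assert 0.0 <= gen <= 2.0


class TestPerformanceMetric:
    @staticmethod
    def _perf(rs, actions):
        from striatal_lsm.readout import _normalize
        return float(np.mean([
            np.linalg.norm(_normalize(r) - _normalize(a))
            for r, a in zip(rs, actions)
        ]))

    def test_aligned_gives_zero(self, rng):
        rs = [rng.random(4) + 0.1 for _ in range(10)]
        assert self._perf(rs, [3.7 * r for r in rs]) == pytest.approx(0.0)

    def test_antipodal_gives_two(self):
        rs = [np.array([1.0, 0, 0, 0])] * 5
        actions = [np.array([-1.0, 0, 0, 0])] * 5
        assert self._perf(rs, actions) == pytest.approx(2.0)

    def test_random_unit_actions_expectation(self):
        """Against a fixed target, uniformly random 4-D unit actions give a
        mean mismatch matching a Monte-Carlo evaluation of E|u - v|."""
        rng = np.random.default_rng(0)
        r = np.array([1.0, 0, 0, 0])
        actions = rng.normal(size=(20_000, 4))
        actions /= np.linalg.norm(actions, axis=1, keepdims=True)
        measured = self._perf([r] * len(actions), actions)
        # independent oracle: E sqrt(2 - 2*u1) under uniform measure on S^3
        u1 = rng.normal(size=(200_000, 4))
        u1 = (u1 / np.linalg.norm(u1, axis=1, keepdims=True))[:, 0]
        oracle = np.sqrt(2 - 2 * u1).mean()
        assert measured == pytest.approx(oracle, abs=0.02)
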