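"""Target functions: Mackey-Glass map, cardinal rectification, task objects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striatal_lsm.encoding import AgentPosition
from striatal_lsm.tasks import (
    MGParameters,
    MGState,
    MackeyGlassTask,
    cardinalize,
    decardinalize,
    goal_direction,
    make_task,
    mg_orbit,
    mg_step,
)


def _oracle_orbit(n, tau, x0=0.5, y0=0.5, alpha=0.2, beta=0.1, gamma=10.0, eta=15.0):
    """Independent brute-force evaluation of the discretized Mackey-Glass map."""
    xs, ys = [x0], [y0]
    dxs, dys = [], []
    for i in range(n):
        x, y = xs[-1], ys[-1]
        y_del = ys[i - tau] if i - tau >= 0 else y0
        dy = alpha * x / (1.0 + (x / eta) ** gamma) - beta * y
        dx = y_del - x
        dxs.append(dx)
        dys.append(dy)
        xs.append(x + dx)
        ys.append(y + dy)
    return (np.array(xs[:-1]), np.array(ys[:-1]), np.array(dxs), np.array(dys))


class TestMackeyGlassMap:
    def test_origin_fixed_point(self):
        state = MGState(x=0.0, y=0.0, y_history=__import__("collections").deque(
            [0.0] * 5, maxlen=5))
        dy, dx, _ = mg_step(state, MGParameters(tau=5))
        assert dy == 0.0 and dx == 0.0

    def test_nonlinearity_at_eta(self):
        # x = eta -> (x/eta)^gamma = 1 -> dy = alpha*x/2 - beta*y
        state = MGState.initial(MGParameters(tau=5), x0=15.0, y0=0.0)
        state.y_history = __import__("collections").deque([0.0] * 5, maxlen=5)
        dy, dx, _ = mg_step(state, MGParameters(tau=5))
        assert dy == pytest.approx(0.2 * 15.0 / 2.0)

    @pytest.mark.parametrize("tau", [5, 15])
    def test_orbit_matches_independent_oracle(self, tau):
        xs, ys, dxs, dys = mg_orbit(MGParameters(tau=tau), 100)
        oxs, oys, odxs, odys = _oracle_orbit(100, tau)
        np.testing.assert_allclose(xs, oxs, rtol=1e-12)
        np.testing.assert_allclose(ys, oys, rtol=1e-12)
        np.testing.assert_allclose(dxs, odxs, rtol=1e-12)
        np.testing.assert_allclose(dys, odys, rtol=1e-12)

    @pytest.mark.parametrize("tau", [5, 15])
    def test_orbit_bounded(self, tau):
        xs, ys, _, _ = mg_orbit(MGParameters(tau=tau), 10_000)
        assert np.all(np.isfinite(xs)) and np.all(np.isfinite(ys))
        assert xs.max() < 100 and ys.max() < 100
        assert xs.min() > -100

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MGParameters(tau=0)
        with pytest.raises(ValueError):
            MGParameters(eta=0.0)


class TestCardinalize:
    def test_examples(self):
        np.testing.assert_allclose(cardinalize(1.0, 0.0), [1, 0, 0, 0])
        np.testing.assert_allclose(cardinalize(-2.0, 3.0), [0, 2, 3, 0])

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(deadline=None, max_examples=50)
    def test_decardinalize_inverts(self, dx, dy):
        np.testing.assert_allclose(
            decardinalize(cardinalize(dx, dy)), [dx, dy], atol=1e-12
        )

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(deadline=None, max_examples=50)
    def test_norm_preserved(self, dx, dy):
        assert np.linalg.norm(cardinalize(dx, dy)) == pytest.approx(
            np.hypot(dx, dy), abs=1e-9
        )


class TestGoalDirection:
    def test_due_east_of_goal_points_west(self):
        r = goal_direction(AgentPosition(0.9, 0.5), AgentPosition(0.5, 0.5))
        np.testing.assert_allclose(r, [0, 1, 0, 0], atol=1e-12)

    def test_at_goal_zero_vector(self):
        r = goal_direction(AgentPosition(0.5, 0.5), AgentPosition(0.5, 0.5))
        np.testing.assert_array_equal(r, np.zeros(4))

    def test_diagonal_normalized(self):
        r = goal_direction(AgentPosition(0.0, 0.0), AgentPosition(0.5, 0.5))
        np.testing.assert_allclose(r, [1 / np.sqrt(2), 0, 1 / np.sqrt(2), 0])


class TestMakeTask:
    def test_goal_at_center_zero_target(self):
        task = make_task("GOAL")
        r = task.target(0, AgentPosition(0.5, 0.5))
        np.testing.assert_array_equal(r, np.zeros(4))

    def test_goal_target_unit_magnitude(self, rng):
        task = make_task("GOAL")
        for _ in range(20):
            pos = AgentPosition(*rng.uniform(0, 1, size=2))
            if (pos.x, pos.y) != (0.5, 0.5):
                assert np.linalg.norm(task.target(0, pos)) == pytest.approx(1.0)

    def test_goal_resets_periodically(self, rng):
        task = make_task("GOAL", reset_interval=10)
        pos = AgentPosition(0.1, 0.1)
        assert task.maybe_reset(5, pos, rng) is pos
        assert task.maybe_reset(10, pos, rng) is not pos

    def test_mg5_targets_match_oracle_increments(self):
        task = make_task("MG5")
        _, _, odxs, odys = _oracle_orbit(10, 5)
        for i in range(10):
            r = task.target(i, None)
            net = decardinalize(r)
            assert net[0] == pytest.approx(task._kx * odxs[i], rel=1e-9)
            assert net[1] == pytest.approx(task._ky * odys[i], rel=1e-9)

    def test_mg_positions_inside_central_region(self):
        task = make_task("MG15")
        pos = task.positions
        assert pos.min() >= 0.1 - 1e-9
        assert pos.max() <= 0.9 + 1e-9

    def test_mg15_trajectory_self_crosses(self):
        """The tau=15 trajectory must cross itself (memory is required to
        disambiguate the correct action at the crossing)."""
        task = make_task("MG15")
        seg = task.positions[200:1200]

        def cross2(u, v):
            return u[0] * v[1] - u[1] * v[0]

        def intersects(p1, p2, p3, p4):
            d1 = cross2(p4 - p3, p1 - p3)
            d2 = cross2(p4 - p3, p2 - p3)
            d3 = cross2(p2 - p1, p3 - p1)
            d4 = cross2(p2 - p1, p4 - p1)
            return (d1 * d2 < 0) and (d3 * d4 < 0)

        found = False
        for i in range(0, len(seg) - 1, 5):
            for j in range(i + 10, len(seg) - 1, 5):
                if intersects(seg[i], seg[i + 1], seg[j], seg[j + 1]):
                    found = True
                    break
            if found:
                break
        assert found

    def test_mg_prescribes_positions_goal_does_not(self):
        assert make_task("MG5").position(3) is not None
        assert make_task("GOAL").position(3) is None

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            make_task("SPIRAL")
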