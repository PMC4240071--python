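"""Target functions on the plane for the readout learning experiments.

Three tasks are defined, each mapping an agent state to a 4-vector ``r``
over the cardinal directions (E, W, N, S):

* ``GOAL`` -- unit steps straight toward a goal at the center of the plane,
  with the agent teleported to a random position every few steps;
* ``MG5`` / ``MG15`` -- a discretized delay Mackey-Glass system

      dy_i = alpha * x_i / (1 + (x_i / eta)^gamma) - beta * y_i
      dx_i = y_{i - tau} - x_i

  with alpha=0.2, beta=0.1, gamma=10, eta=15 and delay tau of 5 or 15
  steps.  The (x, y) orbit is mapped affinely into the central 80% of the
  environment; the target at step i is the rectified scaled increment
  (dx_i, dy_i).  The starting position is fixed and there are no resets;
  larger delays couple the target to older inputs and therefore demand more
  fading memory from the network.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import AgentPosition

__all__ = [
    "MGParameters",
    "MGState",
    "TargetDirection",
    "mg_step",
    "mg_orbit",
    "goal_direction",
    "cardinalize",
    "make_task",
    "TASK_NAMES",
]

TASK_NAMES = ("GOAL", "MG5", "MG15")


@dataclass(frozen=True)
class MGParameters:
    """Constants of the discretized Mackey-Glass system."""

    alpha: float = 0.2
    beta: float = 0.1
    gamma: float = 10.0
    eta: float = 15.0
    tau: int = 5

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.tau < 1:
            raise ValueError("tau must be at least 1")


@dataclass
class MGState:
    """Current (x, y) values plus the delayed-y ring buffer."""

    x: float
    y: float
    y_history: deque

    @classmethod
    def initial(cls, params: MGParameters, x0: float = 0.5, y0: float = 0.5) -> "MGState":
        return cls(x=x0, y=y0, y_history=deque([y0] * params.tau, maxlen=params.tau))


def mg_step(state: MGState, params: MGParameters):
    """One update of the discretized Mackey-Glass system.

    Returns ``(dy, dx, new_state)``; the state is advanced in place and the
    history updated (``y_history[0]`` is y from tau steps ago).
    """
    if len(state.y_history) < params.tau:
        raise ValueError("y history must be primed with tau values")
    x, y = state.x, state.y
    dy = params.alpha * x / (1.0 + (x / params.eta) ** params.gamma) - params.beta * y
    dx = state.y_history[0] - x
    state.y_history.append(y)  # deque(maxlen=tau) drops y_{i-tau}
    state.x = x + dx
    state.y = y + dy
    return dy, dx, state


def mg_orbit(params: MGParameters, n_steps: int, x0: float = 0.5, y0: float = 0.5):
    """Iterate the map; returns arrays x, y, dx, dy of length ``n_steps``."""
    state = MGState.initial(params, x0, y0)
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    dxs = np.empty(n_steps)
    dys = np.empty(n_steps)
    for i in range(n_steps):
        xs[i], ys[i] = state.x, state.y
        dys[i], dxs[i], state = mg_step(state, params)
    return xs, ys, dxs, dys


def cardinalize(dx: float, dy: float) -> np.ndarray:
    """Signed plane vector -> non-negative (E, W, N, S) components."""
    return np.array([max(dx, 0.0), max(-dx, 0.0), max(dy, 0.0), max(-dy, 0.0)])


def decardinalize(r) -> np.ndarray:
    """(E, W, N, S) -> signed plane vector (E - W, N - S)."""
    r = np.asarray(r, dtype=float)
    return np.array([r[0] - r[1], r[2] - r[3]])


def goal_direction(pos: AgentPosition, goal: AgentPosition) -> np.ndarray:
    """Unit step toward the goal, rectified into cardinal components."""
    d = goal.as_array() - pos.as_array()
    norm = np.linalg.norm(d)
    if norm == 0:
        return np.zeros(4)
    return cardinalize(*(d / norm))


class TargetFunction:
    """Stateful target: ``r = target(step, pos)`` plus a movement policy.

    ``position(step)`` returns the prescribed agent position for tasks whose
    trajectory is generated by the task itself (the Mackey-Glass tasks), or
    None for tasks where the agent moves according to the advocated action.
    """

    name: str

    def initial_position(self, rng) -> AgentPosition:
        raise NotImplementedError

    def maybe_reset(self, step: int, pos: AgentPosition, rng) -> AgentPosition:
        """Position override applied before step ``step``; identity when none."""
        return pos

    def position(self, step: int) -> AgentPosition | None:
        return None

    def target(self, step: int, pos: AgentPosition) -> np.ndarray:
        raise NotImplementedError


class GoalTask(TargetFunction):
    """Straight trajectories toward a goal at the center of the plane."""

    name = "GOAL"

    def __init__(self, env_width: float = 1.0, reset_interval: int = 10):
        self.env_width = env_width
        self.goal = AgentPosition(env_width / 2, env_width / 2)
        self.reset_interval = reset_interval

    def initial_position(self, rng) -> AgentPosition:
        return AgentPosition(*rng.uniform(0, self.env_width, size=2))

    def maybe_reset(self, step, pos, rng):
        if step > 0 and step % self.reset_interval == 0:
            return self.initial_position(rng)
        return pos

    def target(self, step, pos):
        return goal_direction(pos, self.goal)


class MackeyGlassTask(TargetFunction):
    """Targets from a fixed discretized Mackey-Glass reference orbit.

    The orbit's bounding box (measured over a reference orbit) is mapped
    affinely into the central ``fill`` fraction of the environment; the
    target at step i is the rectified, identically scaled increment.  The
    target sequence is a function of the step index (the trajectory is
    generated by the equations, not by the agent).
    """

    def __init__(
        self,
        tau: int,
        env_width: float = 1.0,
        n_steps: int = 10_000,
        fill: float = 0.8,
        params: MGParameters | None = None,
    ):
        self.name = f"MG{tau}"
        self.env_width = env_width
        self.params = params or MGParameters(tau=tau)
        n_ref = max(n_steps, 10_000)
        xs, ys, dxs, dys = mg_orbit(self.params, n_ref)
        margin = (1.0 - fill) / 2.0
        span_x = xs.max() - xs.min()
        span_y = ys.max() - ys.min()
        self._kx = fill * env_width / span_x if span_x > 0 else 0.0
        self._ky = fill * env_width / span_y if span_y > 0 else 0.0
        self._x0 = margin * env_width - self._kx * xs.min()
        self._y0 = margin * env_width - self._ky * ys.min()
        self.positions = np.column_stack(
            [self._kx * xs + self._x0, self._ky * ys + self._y0]
        )
        self.increments = np.column_stack([self._kx * dxs, self._ky * dys])

    def initial_position(self, rng) -> AgentPosition:
        return AgentPosition(*self.positions[0])

    def position(self, step):
        if step >= len(self.positions):
            raise IndexError(
                f"step {step} beyond the {len(self.positions)}-step reference orbit"
            )
        return AgentPosition(*np.clip(self.positions[step], 0, self.env_width))

    def target(self, step, pos):
        if step >= len(self.increments):
            raise IndexError(
                f"step {step} beyond the {len(self.increments)}-step reference orbit"
            )
        return cardinalize(*self.increments[step])


def make_task(name: str, *, env_width: float = 1.0, n_steps: int = 10_000,
              reset_interval: int = 10, **kwargs) -> TargetFunction:
    """Construct a named task: ``GOAL``, ``MG5`` or ``MG15``."""
    name = name.upper()
    if name == "GOAL":
        return GoalTask(env_width=env_width, reset_interval=reset_interval)
    if name.startswith("MG"):
        try:
            tau = int(name[2:])
        except ValueError:
            raise ValueError(f"unknown task {name!r}") from None
        return MackeyGlassTask(tau, env_width=env_width, n_steps=n_steps, **kwargs)
    raise ValueError(f"unknown task {name!r}; expected one of {TASK_NAMES}")


def export_trajectory(task: TargetFunction, n_steps: int, seed: int = 0) -> pd.DataFrame:
    """Tabulate a task's own trajectory and targets as a DataFrame."""
    rng = np.random.default_rng(seed)
    pos = task.initial_position(rng)
    rows = []
    for step in range(n_steps):
        pos = task.maybe_reset(step, pos, rng)
        r = task.target(step, pos)
        rows.append({"step": step, "x": pos.x, "y": pos.y,
                     "r_E": r[0], "r_W": r[1], "r_N": r[2], "r_S": r[3]})
        if isinstance(task, MackeyGlassTask):
            pos = AgentPosition(*np.clip(
                pos.as_array() + decardinalize(r), 0, task.env_width))
        else:
            step_vec = decardinalize(r)
            pos = AgentPosition(*np.clip(
                pos.as_array() + 0.02 * step_vec, 0, task.env_width))
    return pd.DataFrame(rows)
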