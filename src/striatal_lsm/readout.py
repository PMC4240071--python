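"""Linear perceptron readout of the striatal liquid state.

Four perceptrons, one per cardinal direction, read the low-pass filtered
striatal activity.  Protocol per 300 ms agent step: the agent sits at its
position for 50 ms, the advocated action is computed as ``a = W s(t+50)``,
the weights are then updated over the next 50 simulation steps (5 ms) with
a variant of the perceptron rule,

    dW = sum_{k=1..50} lr * (r/|r| - a/|a|) s(t + 50 + 0.1 k)^T,

(``r`` the correct direction for the task), and after the remaining 245 ms
the agent moves according to the advocated action.  Readout learning is
strictly downstream: it never alters the circuit or its dynamics.

Performance is the average over test steps of ``|r/|r| - a/|a||`` (0 best,
2 worst); generalization is the average of ``|a/|a| - a*/|a*||`` where
``a*`` is advocated by a twin network whose agent sits a few micrometers
away (shift distance ~ N(4, 4/3) um, angle uniform) but which otherwise
sees an identical background realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuit import Circuit
from .encoding import AgentPosition, EncodingParameters, position_to_currents
from .engine import Network
from .tasks import TargetFunction, decardinalize

__all__ = [
    "TrainingSchedule",
    "TrainResult",
    "advocate",
    "perceptron_update",
    "action_to_move",
    "ReadoutSession",
    "train",
    "performance",
    "generalization",
]


@dataclass(frozen=True)
class TrainingSchedule:
    """Timing and learning constants of the readout protocol (times in ms)."""

    step_duration: float = 300.0
    read_latency: float = 50.0
    learn_samples: int = 50
    learn_sample_dt: float = 0.1
    n_train: int = 3000
    n_test: int = 500
    learning_rate: float = 0.01
    step_size: float = 0.02
    shift_mean_um: float = 4.0
    shift_std_um: float = 4.0 / 3.0
    env_width_um: float = 1000.0

    def __post_init__(self) -> None:
        if (
            self.read_latency + self.learn_samples * self.learn_sample_dt
            > self.step_duration
        ):
            raise ValueError("learning window does not fit into the step duration")


def _normalize(vec: np.ndarray) -> np.ndarray:
    """v/|v|, with the zero vector mapped to itself."""
    n = np.linalg.norm(vec)
    return vec / n if n > 0 else np.zeros_like(vec)


def advocate(weights: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Action 4-vector a = W s for a liquid-state vector s."""
    weights = np.asarray(weights)
    s = np.asarray(s)
    if weights.ndim != 2 or weights.shape[1] != s.shape[0]:
        raise ValueError(
            f"weight shape {weights.shape} does not match state length {s.shape}"
        )
    return weights @ s

def perceptron_update(
    weights: np.ndarray,
    r: np.ndarray,
    a: np.ndarray,
    s_samples: np.ndarray,
    learning_rate: float,
) -> np.ndarray:
    """Accumulated perceptron step over the liquid-state samples.

    Returns dW = sum_k lr * (r/|r| - a/|a|) s_k^T; a zero-norm action or
    target contributes as the zero vector.
    """
    s_samples = np.atleast_2d(np.asarray(s_samples))
    if s_samples.shape[1] != weights.shape[1]:
        raise ValueError("liquid samples do not match the weight matrix")
    err = _normalize(np.asarray(r, dtype=float)) - _normalize(np.asarray(a, dtype=float))
    return learning_rate * np.outer(err, s_samples.sum(axis=0))


def action_to_move(a: np.ndarray, step_size: float) -> np.ndarray:
    """Normalized displacement advocated by an action; zero action -> no move."""
    net = decardinalize(a)
    norm = np.linalg.norm(net)
    if norm == 0:
        return np.zeros(2)
    return step_size * net / norm


class ReadoutSession:
    """Closed-loop training/evaluation of the readout on a circuit.

    All randomness (agent resets, background noise, generalization shifts)
    derives from ``seed``; identical seeds give identical weights and logs.
    """

    def __init__(
        self,
        circuit: Circuit,
        task: TargetFunction,
        schedule: TrainingSchedule = TrainingSchedule(),
        enc: EncodingParameters = EncodingParameters(),
        seed: int = 0,
        dt: float = 0.1,
        tau0: float = 20.0,
    ):
        self.circuit = circuit
        self.task = task
        self.schedule = schedule
        self.enc = enc
        self.dt = dt
        indptr, post, weight = circuit.to_csr()
        self._net_args = (circuit.n_cortex, circuit.n_msn, circuit.n_fsi,
                          indptr, post, weight)
        self.net = Network(*self._net_args, dt=dt, tau0=tau0)
        self.weights = np.zeros((4, circuit.n_msn + circuit.n_fsi))
        self.rng = np.random.default_rng(seed)
        self.pos = task.initial_position(self.rng)
        self.step_index = 0
        self.log_rows = []
        # chunk lengths in integration steps
        self._pre = int(round(schedule.read_latency / dt))
        self._learn = schedule.learn_samples
        total = int(round(schedule.step_duration / dt))
        self._post = total - self._pre - self._learn
        if self._post < 0:
            raise ValueError("schedule does not fit into the step duration")
        self._p_bg = enc.poisson_rate * dt * 1e-3

    # -- internals -----------------------------------------------------------

    def _bg(self, n_steps: int, rng) -> np.ndarray:
        return (rng.random((n_steps, self.net.n_ctx)) < self._p_bg).astype(np.uint8)

    def _run(self, net, n_steps, pos, bg, record_every=0):
        dc = np.zeros(net.n_total)
        dc[: net.n_ctx] = position_to_currents(pos, self.enc)
        return net.run(
            n_steps,
            dc=dc,
            bg_spikes=bg,
            bg_targets=np.arange(net.n_ctx, dtype=np.int64),
            bg_weights=np.full(net.n_ctx, self.enc.poisson_weight),
            record_liquid_every=record_every,
        )

    def _shifted(self, pos: AgentPosition) -> AgentPosition:
        d_env = (
            self.rng.normal(self.schedule.shift_mean_um, self.schedule.shift_std_um)
            / self.schedule.env_width_um
            * self.enc.env_width
        )
        phi = self.rng.uniform(0, 2 * np.pi)
        shifted = pos.as_array() + d_env * np.array([np.cos(phi), np.sin(phi)])
        return AgentPosition(*np.clip(shifted, 0, self.enc.env_width))

    def _agent_step(self, learn: bool, twin: Network | None):
        """One 300 ms protocol step; returns (r, a, a_star)."""
        sched = self.schedule
        prescribed = self.task.position(self.step_index)
        if prescribed is not None:
            self.pos = prescribed
        else:
            self.pos = self.task.maybe_reset(self.step_index, self.pos, self.rng)
        pos_star = self._shifted(self.pos) if twin is not None else None
        bg = self._bg(self._pre + self._learn + self._post, self.rng)

        self._run(self.net, self._pre, self.pos, bg[: self._pre])
        s_now = self.net.liquid_state("striatum")
        a = advocate(self.weights, s_now)
        _, _, s_samples = self._run(
            self.net, self._learn, self.pos,
            bg[self._pre: self._pre + self._learn], record_every=1,
        )
        r = self.task.target(self.step_index, self.pos)
        if learn and sched.learning_rate != 0.0:
            self.weights += perceptron_update(
                self.weights, r, a, s_samples[:, self.net.n_ctx:],
                sched.learning_rate,
            )
        self._run(self.net, self._post, self.pos, bg[self._pre + self._learn:])

        a_star = None
        if twin is not None:
            self._run(twin, self._pre, pos_star, bg[: self._pre])
            a_star = advocate(self.weights, twin.liquid_state("striatum"))
            self._run(twin, self._learn + self._post, pos_star, bg[self._pre:])

        self.log_rows.append(
            {"step": self.step_index, "x": self.pos.x, "y": self.pos.y,
             "a_E": a[0], "a_W": a[1], "a_N": a[2], "a_S": a[3],
             "r_E": r[0], "r_W": r[1], "r_N": r[2], "r_S": r[3]}
        )
        if prescribed is None:
            move = action_to_move(a, sched.step_size * self.enc.env_width)
            self.pos = AgentPosition(
                *np.clip(self.pos.as_array() + move, 0, self.enc.env_width)
            )
        self.step_index += 1
        return r, a, a_star

    # -- public API ----------------------------------------------------------

    def train(self, n_steps: int | None = None) -> np.ndarray:
        """Run the training loop; returns the learned weight matrix."""
        n = self.schedule.n_train if n_steps is None else n_steps
        for _ in range(n):
            self._agent_step(learn=True, twin=None)
        return self.weights

    def evaluate(self, n_steps: int | None = None, measure_generalization: bool = True):
        """Frozen-weight test phase; returns (performance, generalization).

        Generalization is None when not measured.
        """
        n = self.schedule.n_test if n_steps is None else n_steps
        twin = None
        if measure_generalization:
            twin = Network(*self._net_args, dt=self.dt, tau0=self.net.tau0)
            # twin continues from the trained network's state
            for name in ("v", "h1", "h2", "i_exc", "i_inh", "s",
                         "last_spike_step", "ring_exc", "ring_inh"):
                setattr(twin, name, getattr(self.net, name).copy())
            twin.step = self.net.step
        perf_terms = []
        gen_terms = []
        for _ in range(n):
            r, a, a_star = self._agent_step(learn=False, twin=twin)
            perf_terms.append(
                np.linalg.norm(_normalize(r) - _normalize(a))
            )
            if a_star is not None:
                gen_terms.append(
                    np.linalg.norm(_normalize(a) - _normalize(a_star))
                )
        perf = float(np.mean(perf_terms)) if perf_terms else np.nan
        gen = float(np.mean(gen_terms)) if gen_terms else None
        return perf, gen

    @property
    def log(self) -> pd.DataFrame:
        return pd.DataFrame(self.log_rows)


@dataclass
class TrainResult:
    weights: np.ndarray
    performance: float
    generalization: float | None
    log: pd.DataFrame


def train(
    circuit: Circuit,
    task: TargetFunction,
    schedule: TrainingSchedule = TrainingSchedule(),
    seed: int = 0,
    *,
    enc: EncodingParameters = EncodingParameters(),
    n_train: int | None = None,
    n_test: int | None = None,
    measure_generalization: bool = True,
) -> TrainResult:
    """Train the readout on a circuit and evaluate it; fully seeded."""
    session = ReadoutSession(circuit, task, schedule, enc, seed)
    session.train(n_train)
    perf, gen = session.evaluate(n_test, measure_generalization)
    return TrainResult(
        weights=session.weights.copy(),
        performance=perf,
        generalization=gen,
        log=session.log,
    )


def performance(result: TrainResult) -> float:
    """Average normalized target/action mismatch over the test steps."""
    return result.performance


def generalization(result: TrainResult) -> float | None:
    """Average normalized action mismatch under micrometer position shifts."""
    return result.generalization
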