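"""Liquid-state filtering, separation measurement and edge-of-chaos analysis.

The liquid state of the network is the vector of exponentially low-pass
filtered spike trains

    ds_j/dt = -s_j/tau0 + (1/tau0) * sum_f delta(t - t^f_j),

with tau0 in seconds: each spike bumps the neuron's trace by ``1/tau0`` and
the trace decays with time constant ``tau0``, so the trace is an
instantaneous rate estimate in spikes/s whose impulse response integrates
to one spike for any ``tau0``.  The separation between two runs u, v at
time t is the Euclidean distance between their liquid-state vectors.

The edge-of-chaos diagnostic perturbs a run with a single extra input spike
and asks whether the separation between the perturbed and unperturbed run is
damped out or amplified: a network is classified chaotic when the natural
logarithm of the (moving-average smoothed) separation is greater than zero
from 200 ms after the perturbation until the end of the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import uniform_filter1d

from .circuit import Circuit, ScaleFactors, build_circuit
from .encoding import AgentPosition, EncodingParameters, position_to_currents
from .engine import Network, SpikeRecord

__all__ = [
    "LiquidState",
    "SeparationCurve",
    "ChaosVerdict",
    "low_pass",
    "separation",
    "separation_curve",
    "separation_experiment",
    "perturbation_experiment",
    "classify_chaos",
    "chaos_frontier",
]


@dataclass
class LiquidState:
    """Filtered traces sampled on a time grid: ``traces[k, j] = s_j(times[k])``."""

    times: np.ndarray
    traces: np.ndarray
    tau0: float

    def at(self, t: float) -> np.ndarray:
        k = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[k] - t) > 1e-6 + 1e-9 * abs(t):
            raise ValueError(f"time {t} not on the sample grid")
        return self.traces[k]


@dataclass
class SeparationCurve:
    """Euclidean state distance over time, with optional perturbation onset."""

    times: np.ndarray
    values: np.ndarray
    perturbation_time: float = 0.0


@dataclass
class ChaosVerdict:
    """Outcome of the perturbation analysis for one network configuration."""

    chaotic: bool
    times: np.ndarray
    log_smoothed: np.ndarray
    onset_time: float


@njit(cache=True)
def _filter_trains(spike_times, train_bounds, sample_times, tau0):
    n_neurons = train_bounds.shape[0] - 1
    n_samples = sample_times.shape[0]
    out = np.zeros((n_samples, n_neurons))
    jump = 1000.0 / tau0  # trace units: spikes/s
    for j in range(n_neurons):
        s = 0.0
        t_prev = 0.0
        f = train_bounds[j]
        end = train_bounds[j + 1]
        for k in range(n_samples):
            t_k = sample_times[k]
            while f < end and spike_times[f] <= t_k:
                s *= np.exp(-(spike_times[f] - t_prev) / tau0)
                s += jump
                t_prev = spike_times[f]
                f += 1
            s *= np.exp(-(t_k - t_prev) / tau0)
            t_prev = t_k
            out[k, j] = s
    return out


def low_pass(record: SpikeRecord, tau0: float, sample_times=None) -> LiquidState:
    """Exact exponential filter of a spike record on a sample grid.

    By default samples on the record's own dt grid, ``dt, 2*dt, ..., T``.
    """
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    if sample_times is None:
        n = int(round(record.duration / record.dt))
        sample_times = (np.arange(n) + 1) * record.dt
    sample_times = np.ascontiguousarray(sample_times, dtype=np.float64)
    bounds = np.zeros(record.n_neurons + 1, dtype=np.int64)
    for j, train in enumerate(record.spikes):
        bounds[j + 1] = bounds[j] + len(train)
    flat = (
        np.concatenate([np.asarray(t, dtype=np.float64) for t in record.spikes])
        if record.n_neurons
        else np.empty(0)
    )
    traces = _filter_trains(flat, bounds, sample_times, float(tau0))
    return LiquidState(times=sample_times, traces=traces, tau0=tau0)


def separation(u: LiquidState, v: LiquidState, t: float) -> float:
    """Euclidean distance between two liquid states at time ``t``."""
    su, sv = u.at(t), v.at(t)
    if su.shape != sv.shape:
        raise ValueError("liquid states cover different neuron sets")
    return float(np.linalg.norm(su - sv))


def separation_curve(u: LiquidState, v: LiquidState) -> SeparationCurve:
    if u.traces.shape != v.traces.shape or not np.allclose(u.times, v.times):
        raise ValueError("liquid states are not on a common grid")
    vals = np.linalg.norm(u.traces - v.traces, axis=1)
    return SeparationCurve(times=u.times.copy(), values=vals)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


def _run_fixed_position(
    net: Network,
    pos: AgentPosition,
    enc: EncodingParameters,
    n_steps: int,
    bg_spikes: np.ndarray,
    extra_event=None,
    record_every: int = 10,
):
    """Drive a full circuit network with a fixed encoded position.

    ``bg_spikes`` is the shared cortical background realization; an optional
    ``extra_event = (ctx_neuron, step)`` injects one additional background
    spike.  Returns the recorded liquid sample matrix (n_samples, n_total).
    """
    n_ctx = net.n_ctx
    dc = np.zeros(net.n_total)
    dc[:n_ctx] = position_to_currents(pos, enc)
    bg = bg_spikes
    if extra_event is not None:
        bg = bg_spikes.copy()
        neuron, step = extra_event
        bg[step, neuron] += 1
    _, _, s = net.run(
        n_steps,
        dc=dc,
        bg_spikes=bg,
        bg_targets=np.arange(n_ctx, dtype=np.int64),
        bg_weights=np.full(n_ctx, enc.poisson_weight),
        record_liquid_every=record_every,
    )
    return s


def _random_position_pair(rng, epsilon: float, env_width: float):
    """Two positions a fixed distance apart, both inside the environment."""
    for _ in range(1000):
        p = rng.uniform(0, env_width, size=2)
        phi = rng.uniform(0, 2 * np.pi)
        q = p + epsilon * env_width * np.array([np.cos(phi), np.sin(phi)])
        if 0 <= q[0] <= env_width and 0 <= q[1] <= env_width:
            return AgentPosition(*p), AgentPosition(*q)
    raise RuntimeError("could not place a position pair inside the environment")


def separation_experiment(
    epsilon: float,
    *,
    n_instantiations: int = 5,
    n_pairs: int = 5,
    scale: ScaleFactors = ScaleFactors(),
    seed: int = 0,
    duration: float = 1000.0,
    enc: EncodingParameters = EncodingParameters(),
    record_every: int = 10,
    circuit_kwargs: dict | None = None,
):
    """Average input- and output-level separation for position offset epsilon.

    For each circuit instantiation and each random position pair at distance
    ``epsilon * env_width``, the network is simulated twice from identical
    initial conditions with an identical background realization; only the
    encoded position differs.  Euclidean distances between the low-pass
    filtered cortical (input) and striatal (output) activities are averaged
    over all ``n_instantiations * n_pairs`` samples.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    rng = np.random.default_rng(seed)
    dt = 0.1
    n_steps = int(round(duration / dt))
    kw = circuit_kwargs or {}
    acc_in = acc_out = None
    for i in range(n_instantiations):
        circuit = build_circuit(scale=scale, seed=int(rng.integers(2**31)), **kw)
        indptr, post, weight = circuit.to_csr()
        for _ in range(n_pairs):
            p, q = _random_position_pair(rng, epsilon, enc.env_width)
            bg_seed = int(rng.integers(2**31))
            bg = (
                np.random.default_rng(bg_seed).random((n_steps, circuit.n_cortex))
                < enc.poisson_rate * dt * 1e-3
            ).astype(np.uint8)
            traces = []
            for pos in (p, q):
                net = Network(circuit.n_cortex, circuit.n_msn, circuit.n_fsi,
                              indptr, post, weight, dt=dt)
                traces.append(
                    _run_fixed_position(net, pos, enc, n_steps, bg,
                                        record_every=record_every)
                )
            d_in = np.linalg.norm(
                traces[0][:, : circuit.n_cortex] - traces[1][:, : circuit.n_cortex],
                axis=1,
            )
            d_out = np.linalg.norm(
                traces[0][:, circuit.n_cortex:] - traces[1][:, circuit.n_cortex:],
                axis=1,
            )
            acc_in = d_in if acc_in is None else acc_in + d_in
            acc_out = d_out if acc_out is None else acc_out + d_out
    n_samples = n_instantiations * n_pairs
    times = (np.arange(len(acc_in)) + 1) * record_every * dt
    return (
        SeparationCurve(times=times, values=acc_in / n_samples),
        SeparationCurve(times=times, values=acc_out / n_samples),
    )


def perturbation_experiment(
    circuit: Circuit,
    position: AgentPosition,
    duration: float,
    seed: int = 0,
    *,
    perturbation_time: float = 50.0,
    enc: EncodingParameters = EncodingParameters(),
    record_every: int = 1,
) -> SeparationCurve:
    """Separation between a run and its single-extra-spike twin.

    The twin run is identical (same circuit, initial conditions and
    background realization) except that one randomly chosen cortical neuron
    emits one additional spike at ``perturbation_time``: its membrane is
    lifted over threshold so the extra spike propagates through its
    cortico-striatal synapses and perturbs the neuron's own subsequent
    firing.  Returns the striatal-level separation curve.
    """
    if duration <= 200:
        raise ValueError("duration must exceed 200 ms for the chaos verdict")
    dt = 0.1
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    bg = (
        rng.random((n_steps, circuit.n_cortex)) < enc.poisson_rate * dt * 1e-3
    ).astype(np.uint8)
    extra_neuron = int(rng.integers(circuit.n_cortex))
    pre_steps = int(round(perturbation_time / dt))
    indptr, post, weight = circuit.to_csr()
    dc = np.zeros(circuit.n_cortex + circuit.n_striatal)
    dc[: circuit.n_cortex] = position_to_currents(position, enc)
    bg_targets = np.arange(circuit.n_cortex, dtype=np.int64)
    bg_weights = np.full(circuit.n_cortex, enc.poisson_weight)
    traces = []
    for perturb in (False, True):
        net = Network(circuit.n_cortex, circuit.n_msn, circuit.n_fsi,
                      indptr, post, weight, dt=dt)
        chunks = []
        if pre_steps:
            _, _, s0 = net.run(pre_steps, dc=dc, bg_spikes=bg[:pre_steps],
                               bg_targets=bg_targets, bg_weights=bg_weights,
                               record_liquid_every=record_every)
            chunks.append(s0)
        if perturb:
            # lift the chosen neuron over threshold: it spikes (and resets)
            # on the next step through the ordinary dynamics
            net.v[extra_neuron] = net.lif_params.v_threshold + 1.0
        _, _, s1 = net.run(n_steps - pre_steps, dc=dc,
                           bg_spikes=bg[pre_steps:],
                           bg_targets=bg_targets, bg_weights=bg_weights,
                           record_liquid_every=record_every)
        chunks.append(s1)
        traces.append(np.vstack(chunks))
    d = np.linalg.norm(
        traces[0][:, circuit.n_cortex:] - traces[1][:, circuit.n_cortex:], axis=1
    )
    times = (np.arange(len(d)) + 1) * record_every * dt
    return SeparationCurve(times=times, values=d,
                           perturbation_time=perturbation_time)


def classify_chaos(
    curve: SeparationCurve, smoothing_window: float = 50.0, settle: float = 200.0
) -> ChaosVerdict:
    """Chaotic iff ln(moving-average separation) stays > 0 after settling.

    The curve is smoothed with a moving average of width ``smoothing_window``
    (ms); the verdict requires ln(smoothed) > 0 at every sample from
    ``perturbation_time + settle`` to the end of the run.  An identically
    zero tail is non-chaotic (log treated as -inf).
    """
    times, values = curve.times, curve.values
    if times[-1] < curve.perturbation_time + settle:
        raise ValueError("curve too short: need >= 200 ms past the perturbation")
    sample_dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    win = max(1, int(round(smoothing_window / sample_dt)))
    smoothed = uniform_filter1d(values, size=win, mode="nearest")
    with np.errstate(divide="ignore"):
        log_s = np.log(smoothed)
    onset = curve.perturbation_time + settle
    tail = log_s[times >= onset]
    chaotic = bool(len(tail) > 0 and np.all(tail > 0))
    return ChaosVerdict(chaotic=chaotic, times=times, log_smoothed=log_s,
                        onset_time=onset)


def chaos_frontier(
    w_s_values,
    w_c_values,
    *,
    seed: int = 0,
    duration: float = 500.0,
    smoothing_window: float = 50.0,
    enc: EncodingParameters = EncodingParameters(),
    circuit_kwargs: dict | None = None,
    fsi_input_factor: float = 2.0,
):
    """Trace the order/chaos boundary over a (w_s, w_c) grid.

    For every ``w_s`` row, scans ``w_c`` in increasing order and reports the
    smallest value classified chaotic (None if the whole row is ordered).
    Also returns the full verdict grid keyed by ``(w_s, w_c)``.
    """
    rng = np.random.default_rng(seed)
    kw = circuit_kwargs or {}
    pos_seed = int(rng.integers(2**31))
    verdicts = {}
    frontier = {}
    for w_s in w_s_values:
        frontier[w_s] = None
        for w_c in sorted(w_c_values):
            cell_rng = np.random.default_rng((pos_seed, int(w_s * 1000), int(w_c * 1000)))
            circuit = build_circuit(
                scale=ScaleFactors(w_s=w_s, w_c=w_c, fsi_input_factor=fsi_input_factor),
                seed=int(cell_rng.integers(2**31)),
                **kw,
            )
            pos = AgentPosition(*cell_rng.uniform(0, enc.env_width, size=2))
            curve = perturbation_experiment(
                circuit, pos, duration, seed=int(cell_rng.integers(2**31)), enc=enc
            )
            verdict = classify_chaos(curve, smoothing_window=smoothing_window)
            verdicts[(w_s, w_c)] = verdict
            if verdict.chaotic and frontier[w_s] is None:
                frontier[w_s] = w_c
    return frontier, verdicts
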