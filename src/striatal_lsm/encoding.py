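"""Position encoding by a bank of cortical LIF neurons.

The 2-D agent position is encoded by 50 leaky integrate-and-fire neurons:
neurons 0..24 tile the x axis, neurons 25..49 the y axis, each with a
preferred coordinate on a uniform grid.  A neuron receives a weak direct
current with Gaussian magnitude peaking at the encoded coordinate, plus an
independent excitatory Poissonian background at a common rate.  The profile
is clipped at the boundaries (the agent plane is not periodic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Network, SpikeRecord
from .neurons import CTX_LIF_PARAMS, LIFParameters, lif_rheobase

__all__ = ["AgentPosition", "EncodingParameters", "position_to_currents", "cortical_drive"]


@dataclass(frozen=True)
class AgentPosition:
    """Agent coordinates on the task plane, 0 <= x, y <= env_width."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class EncodingParameters:
    """Parameters of the position encoder.

    ``i_max`` defaults to 1.2x the LIF rheobase so neurons at the encoded
    coordinate fire at some tens of spikes/s; ``sigma_idx`` is the Gaussian
    tuning width in neuron-index units.
    """

    n_per_axis: int = 25
    i_max: float = 1.2 * lif_rheobase(CTX_LIF_PARAMS)
    sigma_idx: float = 2.0
    poisson_rate: float = 600.0
    poisson_weight: float = 60.0
    env_width: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_axis < 2:
            raise ValueError("need at least 2 neurons per axis")
        if self.sigma_idx <= 0:
            raise ValueError("sigma_idx must be positive")

    @property
    def n_neurons(self) -> int:
        return 2 * self.n_per_axis

    def grid_spacing(self) -> float:
        return self.env_width / (self.n_per_axis - 1)


def _axis_profile(coord: float, params: EncodingParameters) -> np.ndarray:
    """Gaussian DC profile over one axis' neurons (index space, clipped)."""
    u = coord / params.grid_spacing()  # position in fractional index units
    idx = np.arange(params.n_per_axis)
    return params.i_max * np.exp(-((idx - u) ** 2) / (2 * params.sigma_idx**2))


def position_to_currents(pos: AgentPosition, params: EncodingParameters) -> np.ndarray:
    """DC vector (pA) over the 2*n_per_axis cortical neurons for a position."""
    if not (0 <= pos.x <= params.env_width and 0 <= pos.y <= params.env_width):
        raise ValueError(f"position {pos} outside the environment")
    return np.concatenate(
        [_axis_profile(pos.x, params), _axis_profile(pos.y, params)]
    )


def cortical_bank(
    params: EncodingParameters, lif_params: LIFParameters = CTX_LIF_PARAMS, **kw
) -> Network:
    """A standalone cortical bank (no striatal neurons, no synapses)."""
    n = params.n_neurons
    indptr = np.zeros(n + 1, dtype=np.int64)
    return Network(
        n, 0, 0, indptr, np.empty(0, dtype=np.int64), np.empty(0),
        lif_params=lif_params, **kw,
    )


def cortical_drive(
    pos: AgentPosition,
    params: EncodingParameters,
    duration: float,
    seed: int = 0,
    dt: float = 0.1,
) -> SpikeRecord:
    """Simulate the cortical bank encoding a fixed position.

    Each LIF neuron receives its position-dependent DC plus an independent
    Poisson background train at ``params.poisson_rate``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    net = cortical_bank(params, dt=dt)
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    p = params.poisson_rate * dt * 1e-3
    bg = (rng.random((n_steps, params.n_neurons)) < p).astype(np.uint8)
    ids, steps, _ = net.run(
        n_steps,
        dc=position_to_currents(pos, params),
        bg_spikes=bg,
        bg_targets=np.arange(params.n_neurons, dtype=np.int64),
        bg_weights=np.full(params.n_neurons, params.poisson_weight),
    )
    return SpikeRecord.from_events(ids, steps, dt, duration, ["ctx"] * params.n_neurons)
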