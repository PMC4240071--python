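"""Clock-driven network engine.

A single numba kernel advances the whole network -- cortical LIF input
neurons followed by the striatal MAT populations -- on a fixed time grid
(forward-Euler membrane, exact exponential decay for synaptic currents,
threshold kernels and the liquid low-pass trace).  Synaptic events travel
through a ring buffer implementing a uniform conduction delay.

Conventions (shared with :mod:`striatal_lsm.neurons`): at step ``g`` the
membrane is advanced from time ``g*dt`` to ``(g+1)*dt``; a threshold crossing
detected at that step is recorded with spike time ``(g+1)*dt``.  State is kept
between calls so closed-loop protocols (agent moves, readout training) can
run the network in chunks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .neurons import (
    CTX_LIF_PARAMS,
    FSI_PARAMS,
    LIFParameters,
    MATParameters,
    MSN_PARAMS,
    _MOHM_PA_TO_MV,
)

__all__ = ["SpikeRecord", "Network", "run_network"]


# ---------------------------------------------------------------------------
# spike records
# ---------------------------------------------------------------------------


@dataclass
class SpikeRecord:
    """Per-neuron ordered spike times over a simulation run.

    ``spikes[i]`` is a sorted float array of spike times (ms) of neuron ``i``;
    ``labels[i]`` is its population tag (``"ctx"``, ``"msn"`` or ``"fsi"``).
    """

    spikes: list
    duration: float
    dt: float
    labels: list

    def __post_init__(self) -> None:
        if len(self.spikes) != len(self.labels):
            raise ValueError("spikes and labels must have equal length")

    @property
    def n_neurons(self) -> int:
        return len(self.spikes)

    def neurons_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == label)

    def subset(self, indices) -> "SpikeRecord":
        indices = np.asarray(indices)
        return SpikeRecord(
            spikes=[self.spikes[i] for i in indices],
            duration=self.duration,
            dt=self.dt,
            labels=[self.labels[i] for i in indices],
        )

    def total_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    @classmethod
    def from_events(cls, neuron_ids, steps, dt, duration, labels) -> "SpikeRecord":
        """Build from parallel event arrays; spike time is ``(step + 1) * dt``."""
        neuron_ids = np.asarray(neuron_ids)
        times = (np.asarray(steps, dtype=np.int64) + 1) * dt
        n = len(labels)
        order = np.argsort(neuron_ids, kind="stable")
        neuron_ids = neuron_ids[order]
        times = times[order]
        bounds = np.searchsorted(neuron_ids, np.arange(n + 1))
        spikes = [times[bounds[i]: bounds[i + 1]] for i in range(n)]
        return cls(spikes=spikes, duration=duration, dt=dt, labels=list(labels))

    # -- text serialization -------------------------------------------------

    def save(self, path) -> None:
        """Write two-column text (neuron_id, time_ms) plus a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            for i, train in enumerate(self.spikes):
                for t in train:
                    fh.write(f"{i} {t:.4f}\n")
        sidecar = {
            "duration": self.duration,
            "dt": self.dt,
            "labels": list(self.labels),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "SpikeRecord":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        n = len(meta["labels"])
        spikes = [[] for _ in range(n)]
        with open(path) as fh:
            for line in fh:
                fields = line.split()
                if not fields:
                    continue
                spikes[int(fields[0])].append(float(fields[1]))
        return cls(
            spikes=[np.asarray(s) for s in spikes],
            duration=meta["duration"],
            dt=meta["dt"],
            labels=meta["labels"],
        )


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_chunk(
    n_steps,
    step0,
    n_ctx,
    n_total,
    inv_tau_m,
    r_eff,
    refr_steps,
    lif_vth,
    lif_vreset,
    omega,
    alpha1,
    alpha2,
    decay_th1,
    decay_th2,
    decay_exc,
    decay_inh,
    decay_s,
    jump_s,
    indptr,
    post,
    weight,
    delay_steps,
    dc,
    bg_spikes,
    bg_targets,
    bg_weights,
    v,
    h1,
    h2,
    i_exc,
    i_inh,
    s,
    last_spike_step,
    ring_exc,
    ring_inh,
    spike_neuron,
    spike_step,
    s_out,
    s_every,
):
    n_spk = 0
    n_samp = 0
    n_bg = bg_targets.shape[0]
    for k in range(n_steps):
        g = step0 + k
        slot = g % delay_steps
        # deliver delayed synaptic events and external background
        for i in range(n_total):
            i_exc[i] += ring_exc[slot, i]
            i_inh[i] += ring_inh[slot, i]
            ring_exc[slot, i] = 0.0
            ring_inh[slot, i] = 0.0
        for b in range(n_bg):
            c = bg_spikes[k, b]
            if c > 0:
                i_exc[bg_targets[b]] += c * bg_weights[b]
        # integrate and test thresholds
        for i in range(n_total):
            current = i_exc[i] + i_inh[i] + dc[i]
            fired = False
            if i < n_ctx:
                if g - last_spike_step[i] < refr_steps[i]:
                    v[i] = lif_vreset
                else:
                    v[i] += inv_tau_m[i] * (-v[i] + r_eff[i] * current)
                    if v[i] >= lif_vth:
                        fired = True
                        v[i] = lif_vreset
                        last_spike_step[i] = g
            else:
                v[i] += inv_tau_m[i] * (-v[i] + r_eff[i] * current)
                j = i - n_ctx
                if g - last_spike_step[i] >= refr_steps[i] and v[i] >= omega[j] + h1[j] + h2[j]:
                    fired = True
                    last_spike_step[i] = g
                    h1[j] += alpha1[j]
                    h2[j] += alpha2[j]
            if fired:
                spike_neuron[n_spk] = i
                spike_step[n_spk] = g
                n_spk += 1
                s[i] += jump_s
                for e in range(indptr[i], indptr[i + 1]):
                    w = weight[e]
                    if w >= 0.0:
                        ring_exc[slot, post[e]] += w
                    else:
                        ring_inh[slot, post[e]] += w
        # record liquid samples (pre-decay: sample reflects time (g+1)*dt)
        if s_every > 0 and (k + 1) % s_every == 0:
            for i in range(n_total):
                s_out[n_samp, i] = s[i]
            n_samp += 1
        # exact exponential decays
        for i in range(n_total):
            i_exc[i] *= decay_exc
            i_inh[i] *= decay_inh
            s[i] *= decay_s
        for j in range(n_total - n_ctx):
            h1[j] *= decay_th1
            h2[j] *= decay_th2
    return n_spk, n_samp


# ---------------------------------------------------------------------------
# python-facing wrapper
# ---------------------------------------------------------------------------


class Network:
    """Stateful network simulator over a fixed synapse table.

    Parameters
    ----------
    n_ctx, n_msn, n_fsi : population sizes; global neuron order is
        ``[ctx | msn | fsi]``.
    indptr, post, weight : CSR synapse table over global source indices;
        positive weights are delivered as excitatory PSCs (decay
        ``tau_syn_exc``), negative as inhibitory (decay ``tau_syn_inh``).
    dt : integration step (ms).
    tau0 : liquid low-pass filter time constant (ms); the trace is kept in
        spikes/s (each spike bumps it by ``1000/tau0``).
    delay : uniform conduction delay (ms), must be a multiple of ``dt``.
    """

    def __init__(
        self,
        n_ctx: int,
        n_msn: int,
        n_fsi: int,
        indptr: np.ndarray,
        post: np.ndarray,
        weight: np.ndarray,
        *,
        dt: float = 0.1,
        lif_params: LIFParameters = CTX_LIF_PARAMS,
        msn_params: MATParameters = MSN_PARAMS,
        fsi_params: MATParameters = FSI_PARAMS,
        tau0: float = 20.0,
        tau_syn_exc: float = 2.0,
        tau_syn_inh: float = 5.0,
        delay: float = 1.0,
    ):
        self.n_ctx = int(n_ctx)
        self.n_msn = int(n_msn)
        self.n_fsi = int(n_fsi)
        self.n_str = self.n_msn + self.n_fsi
        self.n_total = self.n_ctx + self.n_str
        self.dt = float(dt)
        self.tau0 = float(tau0)
        self.lif_params = lif_params
        self.msn_params = msn_params
        self.fsi_params = fsi_params

        if len(indptr) != self.n_total + 1:
            raise ValueError(
                f"indptr length {len(indptr)} does not match {self.n_total} neurons"
            )
        self.indptr = np.ascontiguousarray(indptr, dtype=np.int64)
        self.post = np.ascontiguousarray(post, dtype=np.int64)
        self.weight = np.ascontiguousarray(weight, dtype=np.float64)
        if len(self.post) and self.post.max() >= self.n_total:
            raise ValueError("synapse target index out of range")

        delay_steps = int(round(delay / dt))
        if delay_steps < 1 or abs(delay_steps * dt - delay) > 1e-9:
            raise ValueError("delay must be a positive multiple of dt")
        self.delay_steps = delay_steps

        # per-neuron model constants
        inv_tau = np.empty(self.n_total)
        r_eff = np.empty(self.n_total)
        refr = np.empty(self.n_total, dtype=np.int64)
        inv_tau[: self.n_ctx] = dt / lif_params.tau_m
        r_eff[: self.n_ctx] = lif_params.r_m * _MOHM_PA_TO_MV
        refr[: self.n_ctx] = int(round(lif_params.refractory / dt))
        for sl, p in (
            (slice(self.n_ctx, self.n_ctx + self.n_msn), msn_params),
            (slice(self.n_ctx + self.n_msn, self.n_total), fsi_params),
        ):
            inv_tau[sl] = dt / p.tau_m
            r_eff[sl] = p.r_m * _MOHM_PA_TO_MV
            refr[sl] = int(round(p.refractory / dt))
        self._inv_tau = inv_tau
        self._r_eff = r_eff
        self._refr = np.maximum(refr, 1)

        omega = np.empty(self.n_str)
        a1 = np.empty(self.n_str)
        a2 = np.empty(self.n_str)
        omega[: self.n_msn] = msn_params.omega
        a1[: self.n_msn] = msn_params.alpha1
        a2[: self.n_msn] = msn_params.alpha2
        omega[self.n_msn:] = fsi_params.omega
        a1[self.n_msn:] = fsi_params.alpha1
        a2[self.n_msn:] = fsi_params.alpha2
        self._omega, self._a1, self._a2 = omega, a1, a2
        # threshold kernels must share time constants across the populations
        if (msn_params.tau_th1, msn_params.tau_th2) != (
            fsi_params.tau_th1,
            fsi_params.tau_th2,
        ):
            raise ValueError("MSN and FSI presets must share threshold time constants")
        self._decay_th1 = math.exp(-dt / msn_params.tau_th1)
        self._decay_th2 = math.exp(-dt / msn_params.tau_th2)
        self._decay_exc = math.exp(-dt / tau_syn_exc)
        self._decay_inh = math.exp(-dt / tau_syn_inh)
        self._decay_s = math.exp(-dt / tau0)
        # Eq-of-motion jump 1/tau0 with tau0 in seconds: the trace is an
        # instantaneous rate estimate in spikes/s (impulse response
        # integrates to one spike)
        self._jump_s = 1000.0 / tau0

        self.labels = (
            ["ctx"] * self.n_ctx + ["msn"] * self.n_msn + ["fsi"] * self.n_fsi
        )
        self.reset()

    def reset(self) -> None:
        """Return all dynamic state to the quiescent initial condition."""
        n = self.n_total
        self.v = np.zeros(n)
        self.h1 = np.zeros(self.n_str)
        self.h2 = np.zeros(self.n_str)
        self.i_exc = np.zeros(n)
        self.i_inh = np.zeros(n)
        self.s = np.zeros(n)
        self.last_spike_step = np.full(n, -(10**9), dtype=np.int64)
        self.ring_exc = np.zeros((self.delay_steps, n))
        self.ring_inh = np.zeros((self.delay_steps, n))
        self.step = 0

    # -- chunked execution ---------------------------------------------------

    def run(
        self,
        n_steps: int,
        dc=None,
        bg_spikes=None,
        bg_targets=None,
        bg_weights=None,
        record_liquid_every: int = 0,
    ):
        """Advance ``n_steps`` steps.

        ``dc`` is a per-neuron DC vector (pA, length ``n_total``), constant
        over the chunk.  ``bg_spikes`` is a ``(n_steps, n_bg)`` uint8 array of
        external event counts delivered to ``bg_targets`` with ``bg_weights``
        (pA per event).  Returns ``(spike_neuron, spike_step, s_samples)``;
        ``s_samples`` has one row per ``record_liquid_every`` steps (or is
        empty when 0).
        """
        n_steps = int(n_steps)
        if n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if dc is None:
            dc = np.zeros(self.n_total)
        dc = np.ascontiguousarray(dc, dtype=np.float64)
        if dc.shape != (self.n_total,):
            raise ValueError(
                f"dc has shape {dc.shape}, expected ({self.n_total},)"
            )
        if bg_targets is None:
            bg_targets = np.empty(0, dtype=np.int64)
            bg_weights = np.empty(0, dtype=np.float64)
            bg_spikes = np.empty((n_steps, 0), dtype=np.uint8)
        bg_targets = np.ascontiguousarray(bg_targets, dtype=np.int64)
        bg_weights = np.ascontiguousarray(bg_weights, dtype=np.float64)
        bg_spikes = np.ascontiguousarray(bg_spikes, dtype=np.uint8)
        if bg_spikes.shape != (n_steps, len(bg_targets)):
            raise ValueError("bg_spikes must have shape (n_steps, n_bg)")

        cap = int(np.sum(n_steps // self._refr + 1))
        spike_neuron = np.empty(cap, dtype=np.int64)
        spike_step = np.empty(cap, dtype=np.int64)
        s_every = int(record_liquid_every)
        n_samp_cap = n_steps // s_every if s_every > 0 else 0
        s_out = np.empty((n_samp_cap, self.n_total))

        n_spk, n_samp = _run_chunk(
            n_steps,
            self.step,
            self.n_ctx,
            self.n_total,
            self._inv_tau,
            self._r_eff,
            self._refr,
            self.lif_params.v_threshold,
            self.lif_params.v_reset,
            self._omega,
            self._a1,
            self._a2,
            self._decay_th1,
            self._decay_th2,
            self._decay_exc,
            self._decay_inh,
            self._decay_s,
            self._jump_s,
            self.indptr,
            self.post,
            self.weight,
            self.delay_steps,
            dc,
            bg_spikes,
            bg_targets,
            bg_weights,
            self.v,
            self.h1,
            self.h2,
            self.i_exc,
            self.i_inh,
            self.s,
            self.last_spike_step,
            self.ring_exc,
            self.ring_inh,
            spike_neuron,
            spike_step,
            s_out,
            s_every,
        )
        self.step += n_steps
        return spike_neuron[:n_spk].copy(), spike_step[:n_spk].copy(), s_out[:n_samp]

    @property
    def time(self) -> float:
        """Current simulation time (ms)."""
        return self.step * self.dt

    def liquid_state(self, population: str = "striatum") -> np.ndarray:
        """Current low-pass filtered trace vector of a population."""
        if population == "striatum":
            return self.s[self.n_ctx:].copy()
        if population == "ctx":
            return self.s[: self.n_ctx].copy()
        if population == "all":
            return self.s.copy()
        raise ValueError(f"unknown population {population!r}")


def run_network(
    circuit,
    duration: float,
    *,
    dc=None,
    bg_rate=None,
    bg_weight=None,
    dt: float = 0.1,
    seed: int = 0,
    extra_events=None,
    record_liquid_every: int = 0,
    tau0: float = 20.0,
    **network_kwargs,
):
    """Run a circuit under constant DC and per-neuron Poisson background.

    Parameters
    ----------
    circuit : :class:`striatal_lsm.circuit.Circuit` (or anything exposing
        ``to_csr()`` and population counts).
    duration : simulated time (ms).
    dc : per-neuron DC vector (pA) in global order, or None.
    bg_rate, bg_weight : per-neuron Poisson background rate (spikes/s) and
        event weight (pA); scalars broadcast over all neurons.
    extra_events : optional list of ``(neuron, time_ms, weight_pA)`` triples
        injected on top of the background (used by perturbation analysis).
    seed : seed for the background realization; identical seeds and inputs
        give bit-identical records.

    Returns
    -------
    (SpikeRecord, liquid_samples) -- the second entry is the recorded liquid
    trace matrix (or an empty array when ``record_liquid_every`` is 0).
    """
    indptr, post, weight = circuit.to_csr()
    net = Network(
        circuit.n_cortex,
        circuit.n_msn,
        circuit.n_fsi,
        indptr,
        post,
        weight,
        dt=dt,
        tau0=tau0,
        **network_kwargs,
    )
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)

    rate = np.zeros(net.n_total) if bg_rate is None else np.broadcast_to(
        np.asarray(bg_rate, dtype=float), (net.n_total,)
    ).copy()
    wvec = np.zeros(net.n_total) if bg_weight is None else np.broadcast_to(
        np.asarray(bg_weight, dtype=float), (net.n_total,)
    ).copy()
    active = np.flatnonzero((rate > 0) & (wvec != 0))
    bg_targets = active
    bg_weights = wvec[active]
    p = rate[active] * dt * 1e-3  # spikes/s -> probability per step
    bg_spikes = (rng.random((n_steps, len(active))) < p).astype(np.uint8)

    if extra_events:
        # one extra event column per injected spike (targets may be silent)
        cols = np.zeros((n_steps, len(extra_events)), dtype=np.uint8)
        tg = np.empty(len(extra_events), dtype=np.int64)
        wg = np.empty(len(extra_events), dtype=np.float64)
        for c, (neuron, t_ms, w) in enumerate(extra_events):
            step = int(round(t_ms / dt))
            if not 0 <= step < n_steps:
                raise ValueError(f"extra event at {t_ms} ms outside the run")
            cols[step, c] = 1
            tg[c] = int(neuron)
            wg[c] = float(w)
        bg_spikes = np.hstack([bg_spikes, cols])
        bg_targets = np.concatenate([bg_targets, tg])
        bg_weights = np.concatenate([bg_weights, wg])

    neuron_ids, steps, s_samples = net.run(
        n_steps,
        dc=dc,
        bg_spikes=bg_spikes,
        bg_targets=bg_targets,
        bg_weights=bg_weights,
        record_liquid_every=record_liquid_every,
    )
    record = SpikeRecord.from_events(
        neuron_ids, steps, dt, duration, net.labels
    )
    return record, s_samples
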