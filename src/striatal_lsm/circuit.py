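"""Generation of the spatial striatal microcircuit.

The circuit places 500 medium spiny neurons (MSNs) and 50 fast spiking
interneurons (FSIs) uniformly on a 1 mm x 1 mm plane with periodic
boundaries, and wires four edge types:

* ``FSI->MSN``: every pair within a fixed radius (100 um) connects with a
  fixed probability (74%);
* ``MSN->MSN``: distance-dependent Gaussian profile, pinned so that the
  probability at one standard deviation is 20%;
* ``CTX->MSN`` and ``CTX->FSI``: each striatal neuron receives input from a
  fixed 25% of randomly selected cortical neurons.

Synaptic strengths are drawn uniformly from per-type base ranges and scaled
by two global factors: ``w_s`` multiplies all intra-striatal synapses and
``w_c`` all cortico-striatal ones, with an extra constant factor on
cortex->FSI reflecting the higher sensitivity of FSIs to cortical drive.
Intra-striatal synapses are inhibitory, cortical ones excitatory; the sign
is applied when the circuit is flattened for the engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScaleFactors",
    "SynapseRanges",
    "EdgeList",
    "Circuit",
    "torus_distance",
    "place_neurons",
    "connect_fsi_msn",
    "connect_msn_msn",
    "wire_cortex",
    "draw_weights",
    "build_circuit",
]

EDGE_TYPES = ("FSI_MSN", "MSN_MSN", "CTX_MSN", "CTX_FSI")
INHIBITORY_TYPES = ("FSI_MSN", "MSN_MSN")


@dataclass(frozen=True)
class ScaleFactors:
    """Global synaptic scale factors.

    ``w_s`` multiplies all intra-striatal synapses, ``w_c`` all
    cortico-striatal ones; ``fsi_input_factor`` is an additional constant
    multiplier on cortex->FSI synapses.
    """

    w_s: float = 18.0
    w_c: float = 113.0
    fsi_input_factor: float = 0.35

    def __post_init__(self) -> None:
        if min(self.w_s, self.w_c, self.fsi_input_factor) < 0:
            raise ValueError("scale factors must be non-negative")


@dataclass(frozen=True)
class SynapseRanges:
    """Uniform base weight ranges (pA per spike, pre-scaling) per edge type.

    These are the free calibration constants of the model; the committed
    defaults were tuned so that the reference configuration
    ``{w_s=18, w_c=113}`` reproduces the target striatal activity statistics
    (MSN mean rate near 4 spikes/s, CV mode near 2, ISI band percentages).
    """

    ctx_msn: tuple = (0.0, 20.2)
    ctx_fsi: tuple = (0.0, 20.2)
    fsi_msn: tuple = (4.0, 12.0)
    msn_msn: tuple = (3.25, 9.75)

    def __post_init__(self) -> None:
        for name in ("ctx_msn", "ctx_fsi", "fsi_msn", "msn_msn"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid weight range for {name}: ({lo}, {hi})")

    def for_type(self, edge_type: str) -> tuple:
        return {
            "CTX_MSN": self.ctx_msn,
            "CTX_FSI": self.ctx_fsi,
            "FSI_MSN": self.fsi_msn,
            "MSN_MSN": self.msn_msn,
        }[edge_type]


@dataclass
class EdgeList:
    """Typed edge list; source/target are population-local indices."""

    edge_type: str
    source: np.ndarray
    target: np.ndarray
    weight: np.ndarray = None
    delay: np.ndarray = None

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {self.edge_type!r}")
        self.source = np.asarray(self.source, dtype=np.int64)
        self.target = np.asarray(self.target, dtype=np.int64)
        if self.weight is None:
            self.weight = np.full(len(self.source), np.nan)
        if self.delay is None:
            self.delay = np.full(len(self.source), 1.0)

    def __len__(self) -> int:
        return len(self.source)


def torus_distance(p, q, extent: float = 1.0):
    """Shortest wrap-around Euclidean distance on a square torus.

    Accepts single coordinates or arrays broadcastable to (..., 2).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = np.abs(p - q)
    d = np.minimum(d, extent - d)
    return np.sqrt((d**2).sum(axis=-1))


def place_neurons(n_msn: int, n_fsi: int, extent: float, rng) -> tuple:
    """Uniform i.i.d. positions on [0, extent)^2 for both populations."""
    if n_msn <= 0 or n_fsi <= 0:
        raise ValueError("population counts must be positive")
    msn = rng.uniform(0.0, extent, size=(n_msn, 2))
    fsi = rng.uniform(0.0, extent, size=(n_fsi, 2))
    return msn, fsi


def connect_fsi_msn(
    fsi_positions, msn_positions, extent: float, rng,
    radius: float = 0.1, p: float = 0.74,
) -> EdgeList:
    """Bernoulli(p) connection for each (FSI, MSN) pair within ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = torus_distance(fsi_positions[:, None, :], msn_positions[None, :, :], extent)
    in_radius = d <= radius
    hits = in_radius & (rng.random(d.shape) < p)
    src, tgt = np.nonzero(hits)
    return EdgeList("FSI_MSN", src, tgt)


def connect_msn_msn(
    msn_positions, extent: float, rng,
    sigma: float = 0.2, p_at_sigma: float = 0.2,
) -> EdgeList:
    """Gaussian distance-dependent MSN->MSN connectivity.

    The profile is ``p(d) = p_at_sigma * exp(1/2) * exp(-d^2 / (2 sigma^2))``
    so that ``p(sigma) = p_at_sigma`` exactly.  Self-connections excluded.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    p0 = p_at_sigma * np.exp(0.5)
    if p0 > 1:
        raise ValueError(f"profile exceeds 1 at d=0 (p(0) = {p0:.3f})")
    d = torus_distance(msn_positions[:, None, :], msn_positions[None, :, :], extent)
    prob = p0 * np.exp(-(d**2) / (2 * sigma**2))
    np.fill_diagonal(prob, 0.0)
    hits = rng.random(prob.shape) < prob
    src, tgt = np.nonzero(hits)
    return EdgeList("MSN_MSN", src, tgt)


def wire_cortex(
    n_targets: int, n_cortex: int, rng, fraction: float = 0.25, edge_type: str = "CTX_MSN"
) -> EdgeList:
    """Fixed random cortical fan-in for every striatal neuron.

    Each target receives from exactly ``int(fraction * n_cortex)`` distinct
    cortical sources, chosen once and fixed.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(fraction * n_cortex)
    if k < 1:
        raise ValueError("fraction too small: zero cortical sources per neuron")
    src = np.empty(n_targets * k, dtype=np.int64)
    tgt = np.repeat(np.arange(n_targets, dtype=np.int64), k)
    for j in range(n_targets):
        src[j * k: (j + 1) * k] = rng.choice(n_cortex, size=k, replace=False)
    return EdgeList(edge_type, src, tgt)


def draw_weights(
    edges: EdgeList, base_ranges: SynapseRanges, scale: ScaleFactors, rng
) -> EdgeList:
    """Draw uniform base weights and apply the global scale factors.

    Weights are stored as magnitudes; the inhibitory sign of intra-striatal
    synapses is applied when flattening for the engine.
    """
    lo, hi = base_ranges.for_type(edges.edge_type)
    factor = {
        "FSI_MSN": scale.w_s,
        "MSN_MSN": scale.w_s,
        "CTX_MSN": scale.w_c,
        "CTX_FSI": scale.w_c * scale.fsi_input_factor,
    }[edges.edge_type]
    edges.weight = rng.uniform(lo, hi, size=len(edges)) * factor
    return edges


@dataclass
class Circuit:
    """A fully instantiated striatal microcircuit."""

    msn_positions: np.ndarray
    fsi_positions: np.ndarray
    edges: dict
    extent: float
    scale: ScaleFactors
    n_cortex: int
    delay: float = 1.0

    @property
    def n_msn(self) -> int:
        return len(self.msn_positions)

    @property
    def n_fsi(self) -> int:
        return len(self.fsi_positions)

    @property
    def n_striatal(self) -> int:
        return self.n_msn + self.n_fsi

    def validate(self) -> None:
        for pos in (self.msn_positions, self.fsi_positions):
            if np.any(pos < 0) or np.any(pos >= self.extent):
                raise ValueError("neuron positions outside the plane")
        for etype in self.edges:
            if etype not in EDGE_TYPES:
                raise ValueError(f"forbidden edge type {etype!r}")

    # -- flattening for the engine ------------------------------------------

    def to_csr(self):
        """Flatten all edges into a CSR table over global source indices.

        Global neuron order is ``[ctx | msn | fsi]``; intra-striatal weights
        are emitted negative (inhibitory), cortical ones positive.
        """
        n_ctx, n_msn = self.n_cortex, self.n_msn
        offs = {"CTX": 0, "MSN": n_ctx, "FSI": n_ctx + n_msn}
        src_all, tgt_all, w_all = [], [], []
        for etype, e in self.edges.items():
            s_pop, t_pop = etype.split("_")
            sign = -1.0 if etype in INHIBITORY_TYPES else 1.0
            src_all.append(e.source + offs[s_pop])
            tgt_all.append(e.target + offs[t_pop])
            w_all.append(sign * e.weight)
        n_total = n_ctx + self.n_striatal
        if not src_all:
            return (
                np.zeros(n_total + 1, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0),
            )
        src = np.concatenate(src_all)
        tgt = np.concatenate(tgt_all)
        w = np.concatenate(w_all)
        order = np.argsort(src, kind="stable")
        src, tgt, w = src[order], tgt[order], w[order]
        indptr = np.searchsorted(src, np.arange(n_total + 1))
        return indptr, tgt, w

    # -- serialization -------------------------------------------------------

    def save(self, directory) -> None:
        """JSON metadata + CSV edge list + positions CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "extent": self.extent,
            "n_cortex": self.n_cortex,
            "delay": self.delay,
            "scale": asdict(self.scale),
        }
        (directory / "circuit.json").write_text(json.dumps(meta, indent=1))
        pos = pd.concat(
            [
                pd.DataFrame(
                    {"population": "msn", "x": self.msn_positions[:, 0],
                     "y": self.msn_positions[:, 1]}
                ),
                pd.DataFrame(
                    {"population": "fsi", "x": self.fsi_positions[:, 0],
                     "y": self.fsi_positions[:, 1]}
                ),
            ],
            ignore_index=True,
        )
        pos.to_csv(directory / "positions.csv", index=False)
        rows = []
        for etype, e in self.edges.items():
            rows.append(
                pd.DataFrame(
                    {"type": etype, "source": e.source, "target": e.target,
                     "weight": e.weight, "delay": e.delay}
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(
            directory / "edges.csv", index=False
        )

    @classmethod
    def load(cls, directory) -> "Circuit":
        directory = Path(directory)
        meta = json.loads((directory / "circuit.json").read_text())
        pos = pd.read_csv(directory / "positions.csv")
        msn = pos[pos.population == "msn"][["x", "y"]].to_numpy()
        fsi = pos[pos.population == "fsi"][["x", "y"]].to_numpy()
        edf = pd.read_csv(directory / "edges.csv")
        edges = {}
        for etype, grp in edf.groupby("type"):
            edges[etype] = EdgeList(
                etype,
                grp.source.to_numpy(),
                grp.target.to_numpy(),
                grp.weight.to_numpy(),
                grp.delay.to_numpy(),
            )
        return cls(
            msn_positions=msn,
            fsi_positions=fsi,
            edges=edges,
            extent=meta["extent"],
            scale=ScaleFactors(**meta["scale"]),
            n_cortex=meta["n_cortex"],
            delay=meta["delay"],
        )


def build_circuit(
    *,
    n_msn: int = 500,
    n_fsi: int = 50,
    n_cortex: int = 50,
    extent: float = 1.0,
    scale: ScaleFactors = ScaleFactors(),
    base_ranges: SynapseRanges = SynapseRanges(),
    fsi_radius: float = 0.1,
    fsi_p: float = 0.74,
    msn_sigma: float = 0.2,
    msn_p_at_sigma: float = 0.2,
    ctx_fraction: float = 0.25,
    delay: float = 1.0,
    seed: int = 0,
) -> Circuit:
    """Instantiate a complete circuit: positions, edges and weights."""
    rng = np.random.default_rng(seed)
    msn_pos, fsi_pos = place_neurons(n_msn, n_fsi, extent, rng)
    edges = {
        "FSI_MSN": connect_fsi_msn(fsi_pos, msn_pos, extent, rng,
                                   radius=fsi_radius, p=fsi_p),
        "MSN_MSN": connect_msn_msn(msn_pos, extent, rng,
                                   sigma=msn_sigma, p_at_sigma=msn_p_at_sigma),
        "CTX_MSN": wire_cortex(n_msn, n_cortex, rng, fraction=ctx_fraction,
                               edge_type="CTX_MSN"),
        "CTX_FSI": wire_cortex(n_fsi, n_cortex, rng, fraction=ctx_fraction,
                               edge_type="CTX_FSI"),
    }
    for e in edges.values():
        draw_weights(e, base_ranges, scale, rng)
        e.delay = np.full(len(e), delay)
    circuit = Circuit(
        msn_positions=msn_pos,
        fsi_positions=fsi_pos,
        edges=edges,
        extent=extent,
        scale=scale,
        n_cortex=n_cortex,
        delay=delay,
    )
    circuit.validate()
    return circuit
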