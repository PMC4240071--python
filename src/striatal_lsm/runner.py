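"""Experiment harness: configuration, the random-trajectory statistics
protocol, and (w_s, w_c) parameter sweeps.

The statistics protocol drives the circuit with the position encoder while
the agent jumps to a new uniformly random position every 300 ms, for 100 s
of simulated time by default; activity statistics are averaged over several
independent circuit realizations per configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuit import Circuit, ScaleFactors, SynapseRanges, build_circuit
from .encoding import AgentPosition, EncodingParameters, position_to_currents
from .engine import Network, SpikeRecord
from .liquid import classify_chaos, perturbation_experiment
from .stats import population_summary
from .readout import TrainingSchedule, train as train_readout
from .tasks import make_task

__all__ = [
    "ExperimentConfig",
    "random_trajectory_record",
    "run_sweep",
]


@dataclass
class ExperimentConfig:
    """Resolved configuration for sweeps and single runs."""

    # sweep grids
    w_s_grid: list = field(default_factory=lambda: list(range(0, 31, 3)))
    w_c_grid: list = field(default_factory=lambda: list(range(65, 216, 15)))
    realizations: int = 10
    seed: int = 0
    # circuit
    n_msn: int = 500
    n_fsi: int = 50
    n_cortex: int = 50
    fsi_input_factor: float = 0.35
    base_ranges: dict = field(default_factory=dict)
    # protocol durations (ms)
    stats_duration: float = 100_000.0
    segment_duration: float = 300.0
    chaos_duration: float = 500.0
    run_chaos: bool = False
    # optional readout training per cell
    tasks: list = field(default_factory=list)
    n_train: int = 300
    n_test: int = 100
    # bookkeeping
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.w_s_grid or not self.w_c_grid:
            raise ValueError("sweep grids must be non-empty")
        if self.realizations < 1:
            raise ValueError("need at least one realization per cell")

    def synapse_ranges(self) -> SynapseRanges:
        return SynapseRanges(**{k: tuple(v) for k, v in self.base_ranges.items()})

    def circuit_kwargs(self) -> dict:
        return dict(
            n_msn=self.n_msn,
            n_fsi=self.n_fsi,
            n_cortex=self.n_cortex,
            base_ranges=self.synapse_ranges(),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def random_trajectory_record(
    circuit: Circuit,
    duration: float = 100_000.0,
    seed: int = 0,
    *,
    enc: EncodingParameters = EncodingParameters(),
    dt: float = 0.1,
    segment_duration: float = 300.0,
    network_kwargs: dict | None = None,
) -> SpikeRecord:
    """Simulate the circuit while the agent follows a random trajectory.

    A new uniformly random position is drawn every ``segment_duration`` ms.
    Fully reproducible from ``seed`` (positions and background noise).
    """
    indptr, post, weight = circuit.to_csr()
    net = Network(circuit.n_cortex, circuit.n_msn, circuit.n_fsi,
                  indptr, post, weight, dt=dt, **(network_kwargs or {}))
    rng = np.random.default_rng(seed)
    seg_steps = int(round(segment_duration / dt))
    n_steps_total = int(round(duration / dt))
    p_bg = enc.poisson_rate * dt * 1e-3
    bg_targets = np.arange(net.n_ctx, dtype=np.int64)
    bg_weights = np.full(net.n_ctx, enc.poisson_weight)
    all_ids = []
    all_steps = []
    done = 0
    while done < n_steps_total:
        n = min(seg_steps, n_steps_total - done)
        pos = AgentPosition(*rng.uniform(0, enc.env_width, size=2))
        dc = np.zeros(net.n_total)
        dc[: net.n_ctx] = position_to_currents(pos, enc)
        bg = (rng.random((n, net.n_ctx)) < p_bg).astype(np.uint8)
        ids, steps, _ = net.run(n, dc=dc, bg_spikes=bg,
                                bg_targets=bg_targets, bg_weights=bg_weights)
        all_ids.append(ids)
        all_steps.append(steps)
        done += n
    return SpikeRecord.from_events(
        np.concatenate(all_ids), np.concatenate(all_steps), dt, duration, net.labels
    )


def _cell_statistics(config, w_s, w_c, seed):
    """Aggregate activity statistics for one sweep cell."""
    rng = np.random.default_rng(seed)
    rates, cv_modes = [], []
    for _ in range(config.realizations):
        circuit = build_circuit(
            scale=ScaleFactors(w_s=w_s, w_c=w_c,
                               fsi_input_factor=config.fsi_input_factor),
            seed=int(rng.integers(2**31)),
            **config.circuit_kwargs(),
        )
        record = random_trajectory_record(
            circuit, duration=config.stats_duration,
            seed=int(rng.integers(2**31)),
            segment_duration=config.segment_duration,
        )
        summary = population_summary(record, neurons=record.neurons_of("msn"))
        rates.append(summary.rate_mean)
        if summary.cv_mode is not None:
            cv_modes.append(summary.cv_mode)
    out = {
        "rate_mean": float(np.mean(rates)),
        "rate_std": float(np.std(rates)),
        "cv_mode_mean": float(np.mean(cv_modes)) if cv_modes else np.nan,
        "cv_mode_std": float(np.std(cv_modes)) if cv_modes else np.nan,
    }
    if config.run_chaos:
        circuit = build_circuit(
            scale=ScaleFactors(w_s=w_s, w_c=w_c,
                               fsi_input_factor=config.fsi_input_factor),
            seed=int(rng.integers(2**31)),
            **config.circuit_kwargs(),
        )
        pos = AgentPosition(*rng.uniform(0, 1, size=2))
        curve = perturbation_experiment(
            circuit, pos, config.chaos_duration, seed=int(rng.integers(2**31))
        )
        out["chaotic"] = classify_chaos(curve).chaotic
    for task_name in config.tasks:
        circuit = build_circuit(
            scale=ScaleFactors(w_s=w_s, w_c=w_c,
                               fsi_input_factor=config.fsi_input_factor),
            seed=int(rng.integers(2**31)),
            **config.circuit_kwargs(),
        )
        task = make_task(task_name)
        result = train_readout(
            circuit, task,
            TrainingSchedule(n_train=config.n_train, n_test=config.n_test),
            seed=int(rng.integers(2**31)),
            measure_generalization=True,
        )
        out[f"performance_{task_name}"] = result.performance
        out[f"generalization_{task_name}"] = result.generalization
    return out


def run_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full (w_s, w_c) sweep described by ``config``.

    Every cell aggregates ``config.realizations`` independent circuit
    realizations; the per-cell seed derives deterministically from
    ``config.seed`` so a rerun reproduces the table exactly.  When
    ``config.output_dir`` is set, the resolved config and the result table
    are written there.
    """
    rows = []
    for w_s in config.w_s_grid:
        for w_c in config.w_c_grid:
            cell_seed = int(
                np.random.default_rng(
                    (config.seed, int(w_s * 1000), int(w_c * 1000))
                ).integers(2**31)
            )
            try:
                cell = _cell_statistics(config, w_s, w_c, cell_seed)
                cell["complete"] = True
            except Exception as exc:  # pragma: no cover - partial failure path
                cell = {"complete": False, "error": str(exc)}
            rows.append({"w_s": w_s, "w_c": w_c, "seed": cell_seed, **cell})
    result = pd.DataFrame(rows)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
        result.to_csv(out / "sweep.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps({"seed": config.seed,
                        "cell_seeds": result[["w_s", "w_c", "seed"]].to_dict("records")})
        )
    return result
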