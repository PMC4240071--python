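"""Spike-train statistics used to validate the circuit against physiology.

Per neuron: firing rate, interspike intervals (ISIs), the coefficient of
variation CV = std(ISI)/mean(ISI) (a global regularity measure) and the
local coefficient of variation CV2 over adjacent ISI pairs,

    CV2_n = |ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n),

which is bounded in [0, 1] and flags episodic firing when its distribution
is bimodal.  ISIs are additionally classified into the classical ECoG
frequency bands: slow/delta (> 250 ms), theta-alpha (80-250 ms], beta
(30-80 ms] and gamma (<= 30 ms).

Population summaries use the reference histogram bins: rate in 0.1-wide
bins of log10(rate), ISI in 1.2 s bins, CV in 0.5-wide bins and CV2 in
0.05-wide bins.  CV bins are centered on multiples of 0.5 so the reported
mode is itself a multiple of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import SpikeRecord

__all__ = [
    "NeuronStatistics",
    "PopulationSummary",
    "firing_rate",
    "interspike_intervals",
    "coefficient_of_variation",
    "local_cv2",
    "isi_band_fractions",
    "neuron_statistics",
    "population_summary",
    "top_rate_indices",
    "BAND_NAMES",
]

BAND_NAMES = ("slow_delta", "theta_alpha", "beta", "gamma")
#: half-open band edges in ms: gamma (0, 30], beta (30, 80], theta-alpha
#: (80, 250], slow/delta (250, inf)
_BAND_EDGES = (30.0, 80.0, 250.0)


def firing_rate(spikes, duration: float) -> float:
    """Total spike count divided by the simulation time; spikes/s."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(spikes) / (duration * 1e-3)


def interspike_intervals(spikes) -> np.ndarray:
    return np.diff(np.asarray(spikes, dtype=float))


def coefficient_of_variation(isis) -> float:
    """std(ISI)/mean(ISI), population (1/N) standard deviation convention."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) < 2:
        raise ValueError("CV requires at least two interspike intervals")
    return float(np.std(isis) / np.mean(isis))


def local_cv2(isis) -> np.ndarray:
    """CV2 series over adjacent ISI pairs (length N-1 for N ISIs)."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) < 2:
        raise ValueError("CV2 requires at least two interspike intervals")
    a, b = isis[:-1], isis[1:]
    return np.abs(b - a) / (b + a)


def isi_band_fractions(isis) -> dict:
    """Percentage of ISIs in each ECoG band; sums to exactly 100."""
    isis = np.asarray(isis, dtype=float)
    if len(isis) == 0:
        raise ValueError("band fractions require at least one ISI")
    g, b, t = _BAND_EDGES
    counts = np.array(
        [
            np.sum(isis > t),
            np.sum((isis > b) & (isis <= t)),
            np.sum((isis > g) & (isis <= b)),
            np.sum(isis <= g),
        ],
        dtype=float,
    )
    return dict(zip(BAND_NAMES, 100.0 * counts / counts.sum()))


@dataclass
class NeuronStatistics:
    rate: float
    isi: np.ndarray
    cv: float | None
    cv2: np.ndarray | None

    @property
    def band_fractions(self) -> dict | None:
        return isi_band_fractions(self.isi) if len(self.isi) else None


def neuron_statistics(spikes, duration: float) -> NeuronStatistics:
    """All single-train statistics; CV/CV2 are None below 3 spikes."""
    isis = interspike_intervals(spikes)
    enough = len(isis) >= 2
    return NeuronStatistics(
        rate=firing_rate(spikes, duration),
        isi=isis,
        cv=coefficient_of_variation(isis) if enough else None,
        cv2=local_cv2(isis) if enough else None,
    )


def _histogram(values, bin_width, offset=0.0):
    """Density histogram with fixed-width bins; returns (bin_left, density)."""
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return np.empty(0), np.empty(0)
    lo = np.floor((values.min() - offset) / bin_width) * bin_width + offset
    hi = np.ceil((values.max() - offset) / bin_width + 1e-9) * bin_width + offset
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(values, bins=edges)
    return edges[:-1], counts / counts.sum()


@dataclass
class PopulationSummary:
    """Population-level activity statistics of one spike record."""

    rate_mean: float
    rate_std: float
    cv_mode: float | None
    cv_hist: pd.DataFrame
    cv2_hist: pd.DataFrame
    isi_hist: pd.DataFrame
    log_rate_hist: pd.DataFrame
    band_fractions_mean: dict
    band_fractions_std: dict
    n_neurons: int
    n_cv_neurons: int


def population_summary(
    record: SpikeRecord,
    *,
    neurons=None,
    cv_bin: float = 0.5,
    cv2_bin: float = 0.05,
    isi_bin_ms: float = 1200.0,
    log_rate_bin: float = 0.1,
) -> PopulationSummary:
    """Aggregate statistics over a (sub)population of a spike record.

    Neurons with fewer than 3 spikes are excluded from the CV/CV2
    distributions; the CV mode is the center of the fullest CV bin, with
    bins centered on multiples of ``cv_bin``.
    """
    if neurons is None:
        neurons = np.arange(record.n_neurons)
    stats = [neuron_statistics(record.spikes[i], record.duration) for i in neurons]
    if not stats:
        raise ValueError("empty population")
    rates = np.array([st.rate for st in stats])
    cvs = np.array([st.cv for st in stats if st.cv is not None])
    cv2s = (
        np.concatenate([st.cv2 for st in stats if st.cv2 is not None])
        if any(st.cv2 is not None for st in stats)
        else np.empty(0)
    )
    isis = (
        np.concatenate([st.isi for st in stats if len(st.isi)])
        if any(len(st.isi) for st in stats)
        else np.empty(0)
    )
    bands = [st.band_fractions for st in stats if st.band_fractions is not None]

    # CV bins centered on multiples of the bin width
    cv_left, cv_dens = _histogram(cvs, cv_bin, offset=-cv_bin / 2)
    cv_mode = float(cv_left[np.argmax(cv_dens)] + cv_bin / 2) if len(cv_left) else None
    cv2_left, cv2_dens = _histogram(cv2s, cv2_bin)
    isi_left, isi_dens = _histogram(isis, isi_bin_ms)
    with np.errstate(divide="ignore"):
        log_rates = np.log10(rates[rates > 0])
    lr_left, lr_dens = _histogram(log_rates, log_rate_bin)

    band_mean = {
        name: float(np.mean([b[name] for b in bands])) if bands else np.nan
        for name in BAND_NAMES
    }
    band_std = {
        name: float(np.std([b[name] for b in bands])) if bands else np.nan
        for name in BAND_NAMES
    }
    return PopulationSummary(
        rate_mean=float(rates.mean()),
        rate_std=float(rates.std()),
        cv_mode=cv_mode,
        cv_hist=pd.DataFrame({"bin_left": cv_left, "density": cv_dens}),
        cv2_hist=pd.DataFrame({"bin_left": cv2_left, "density": cv2_dens}),
        isi_hist=pd.DataFrame({"bin_left": isi_left, "density": isi_dens}),
        log_rate_hist=pd.DataFrame({"bin_left": lr_left, "density": lr_dens}),
        band_fractions_mean=band_mean,
        band_fractions_std=band_std,
        n_neurons=len(stats),
        n_cv_neurons=len(cvs),
    )


def top_rate_indices(record: SpikeRecord, label: str, n: int = 5) -> np.ndarray:
    """Indices (global) of the ``n`` highest-rate neurons of a population.

    Deterministic: ties are broken by ascending neuron index.
    """
    idx = record.neurons_of(label)
    rates = np.array([firing_rate(record.spikes[i], record.duration) for i in idx])
    order = np.lexsort((idx, -rates))
    return idx[order[:n]]
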