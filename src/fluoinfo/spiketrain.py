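"""Inhomogeneous-Poisson spike generation driven by position through a rate map.

The conditional intensity function (CIF) is the rate-map profile evaluated
along the animal's trajectory, rescaled so its session average equals the
neuron's mean rate exactly.  Spikes are drawn per 1-ms bin as Poisson counts
and binned into 30-Hz mock imaging frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorTrace
from .ratemaps import RateMap, evaluate_ratemap

__all__ = [
    "SpikeTrain",
    "FrameSeries",
    "build_cif",
    "generate_spikes",
    "bin_to_frames",
    "save_spike_times",
    "load_spike_times",
]

SIMULATION_RATE = 1000.0  # Hz
FRAME_RATE = 30.0         # Hz


@dataclass
class SpikeTrain:
    spike_times: np.ndarray          # s, sorted
    simulation_rate: float = SIMULATION_RATE
    duration: float = 0.0            # s

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)


@dataclass
class FrameSeries:
    """Per-frame values: AP counts, dF/F, or transient indicators."""

    values: np.ndarray
    frame_rate: float = FRAME_RATE
    start_time: float = 0.0

    @property
    def times(self) -> np.ndarray:
        """Frame-center times."""
        return self.start_time + (np.arange(len(self.values)) + 0.5) / self.frame_rate


def build_cif(
    map: RateMap,
    trace: BehaviorTrace,
    mean_rate: float | None = None,
    simulation_rate: float = SIMULATION_RATE,
) -> np.ndarray:
    """Per-millisecond firing rate (Hz) along the trajectory.

    Positions are linearly interpolated to the simulation clock, passed
    through the normalized rate-map profile, and the result is rescaled so
    that its average over the whole session equals ``mean_rate`` exactly.
    """
    if mean_rate is None:
        mean_rate = map.mean_rate
    n = int(np.floor(trace.duration * simulation_rate))
    t = (np.arange(n) + 0.5) / simulation_rate
    x = np.interp(t, trace.timestamps, trace.position) / trace.track_length
    x = np.clip(x, 0.0, 1.0)
    rate = evaluate_ratemap(map, x)
    m = rate.mean()
    if m <= 0.0:
        raise ValueError("degenerate rate profile along trajectory")
    return rate * (mean_rate / m)


def generate_spikes(
    cif: np.ndarray,
    seed: int | np.random.Generator = 0,
    simulation_rate: float = SIMULATION_RATE,
) -> SpikeTrain:
    """Draw Poisson spike counts per simulation bin; times at bin centers."""
    cif = np.asarray(cif, dtype=float)
    if np.any(cif < 0):
        raise ValueError("CIF must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.poisson(cif / simulation_rate)
    idx = np.flatnonzero(counts)
    times = np.repeat((idx + 0.5) / simulation_rate, counts[idx])
    return SpikeTrain(times, simulation_rate, duration=len(cif) / simulation_rate)


def bin_to_frames(train: SpikeTrain, frame_rate: float = FRAME_RATE) -> FrameSeries:
    """Integer AP counts per half-open imaging frame [t, t + 1/frame_rate)."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n_frames = int(np.floor(train.duration * frame_rate))
    counts = np.zeros(n_frames, dtype=np.int64)
    if train.n_spikes:
        idx = np.floor(train.spike_times * frame_rate).astype(int)
        idx = idx[(idx >= 0) & (idx < n_frames)]
        np.add.at(counts, idx, 1)
    return FrameSeries(counts, frame_rate)


def save_spike_times(train: SpikeTrain, path) -> None:
    """One spike time (s) per line — also the entry point for real AP data."""
    np.savetxt(path, train.spike_times, fmt="%.6f")


def load_spike_times(path, duration: float | None = None) -> SpikeTrain:
    times = np.sort(np.atleast_1d(np.loadtxt(path)))
    if duration is None:
        duration = float(times[-1]) if len(times) else 0.0
    return SpikeTrain(times, duration=duration)
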