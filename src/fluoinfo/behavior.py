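"""Virtual-linear-track behavior: synthesis, loading, and run-period masking.

Emulates head-fixed mice running down a 3-m virtual track for an end-of-track
reward: forward-only running with stochastic speed fluctuation, occasional
pauses, a reward stop at the track end and a teleport back to the start after
a fixed delay.  Real behavior recordings (two-column delimited text of time
and position) can be loaded and resampled instead of synthesized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BehaviorTrace",
    "RunMask",
    "synth_behavior",
    "assemble_session",
    "run_mask",
    "session_inclusion",
    "load_behavior",
    "save_behavior",
    "speed_trace",
]

TRACK_LENGTH = 3.0       # m
SAMPLE_RATE = 50.0       # Hz
MEAN_SPEED = 19.3        # cm/s, session-average running speed to emulate
TELEPORT_DELAY = 1.5     # s spent at the track end before teleporting


@dataclass
class BehaviorTrace:
    """Uniformly sampled 1-D track position with lap (teleport) structure."""

    timestamps: np.ndarray   # s
    position: np.ndarray     # m, in [0, track_length)
    sample_rate: float       # Hz
    track_length: float = TRACK_LENGTH
    lap_starts: np.ndarray | None = None  # sample indices of teleports

    def __post_init__(self):
        if self.lap_starts is None:
            self.lap_starts = np.flatnonzero(np.diff(self.position) < -self.track_length / 2) + 1

    @property
    def duration(self) -> float:
        return len(self.position) / self.sample_rate

    @property
    def n_laps(self) -> int:
        return len(self.lap_starts) + 1


@dataclass
class RunMask:
    """Boolean per-sample mask of qualifying running periods."""

    mask: np.ndarray
    speed_threshold: float   # cm/s
    min_run: float           # cm


def synth_behavior(
    duration: float,
    mean_speed: float = MEAN_SPEED,
    pause_rate: float = 0.02,
    pause_duration: float = 2.0,
    teleport_delay: float = TELEPORT_DELAY,
    sample_rate: float = SAMPLE_RATE,
    track_length: float = TRACK_LENGTH,
    seed: int | np.random.Generator = 0,
) -> BehaviorTrace:
    """Generate synthetic forward-running track behavior.

    The instantaneous running speed follows an Ornstein-Uhlenbeck process
    around ``mean_speed`` (cm/s), clipped at zero.  Pauses arrive as a
    Poisson process at ``pause_rate`` per second and last an exponential
    time with mean ``pause_duration``.  Reaching the track end freezes the
    animal for ``teleport_delay`` seconds, then teleports it to position 0.
    """
    if duration <= 0 or mean_speed <= 0:
        raise ValueError("duration and mean_speed must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * sample_rate))
    dt = 1.0 / sample_rate

    # OU parameters: relaxation ~2 s, stationary SD ~20% of the mean speed.
    theta = 0.5
    sd = 0.2 * mean_speed
    sigma = sd * np.sqrt(2.0 * theta)

    pos = np.empty(n)
    lap_starts = []
    x = 0.0
    v = mean_speed
    hold = 0.0          # remaining freeze time (pause or teleport delay), s
    teleporting = False
    for i in range(n):
        if hold > 0.0:
            hold -= dt
            if hold <= 0.0 and teleporting:
                x = 0.0
                teleporting = False
                lap_starts.append(i)
            pos[i] = x if not teleporting else pos[i - 1]
            continue
        v += theta * (mean_speed - v) * dt + sigma * np.sqrt(dt) * rng.standard_normal()
        v = max(v, 0.0)
        x = x + v / 100.0 * dt
        if x >= track_length:
            x = np.nextafter(track_length, 0.0)
            hold = teleport_delay
            teleporting = True
        elif rng.random() < pause_rate * dt:
            hold = rng.exponential(pause_duration)
        pos[i] = x
    t = np.arange(n) / sample_rate
    return BehaviorTrace(t, pos, sample_rate, track_length, np.asarray(lap_starts, dtype=int))


def assemble_session(traces: list[BehaviorTrace], target_duration: float) -> BehaviorTrace:
    """Concatenate behavior traces and truncate to a target duration.

    Timestamps are re-based to a single session clock; per-sample positions
    are preserved verbatim (no interpolation across joins) and every join is
    treated as a teleport.
    """
    if not traces:
        raise ValueError("at least one behavior trace is required")
    sr = traces[0].sample_rate
    L = traces[0].track_length
    if any(tr.sample_rate != sr or tr.track_length != L for tr in traces):
        raise ValueError("all traces must share sample_rate and track_length")
    pos = np.concatenate([tr.position for tr in traces])
    laps = []
    offset = 0
    for tr in traces:
        laps.extend(np.asarray(tr.lap_starts) + offset)
        offset += len(tr.position)
        if offset < len(pos):
            laps.append(offset)  # join counts as a teleport
    n = int(round(target_duration * sr))
    if n > len(pos):
        raise ValueError("concatenated traces shorter than the target duration")
    pos = pos[:n]
    laps = np.asarray([i for i in laps if 0 < i < n], dtype=int)
    return BehaviorTrace(np.arange(n) / sr, pos, sr, L, laps)


def speed_trace(trace: BehaviorTrace) -> np.ndarray:
    """Instantaneous speed (cm/s) by centered difference, teleports excluded.

    Samples adjacent to a teleport would otherwise see a ~-3 m jump; their
    speed is taken from the one-sided difference on the valid side.
    """
    p = trace.position * 100.0  # cm
    dt = 1.0 / trace.sample_rate
    v = np.empty_like(p)
    v[1:-1] = (p[2:] - p[:-2]) / (2 * dt)
    v[0] = (p[1] - p[0]) / dt
    v[-1] = (p[-1] - p[-2]) / dt
    for i in np.asarray(trace.lap_starts):
        if i >= 1:
            v[i - 1] = (p[i - 1] - p[i - 2]) / dt if i >= 2 else 0.0
        if i < len(p):
            v[i] = (p[i + 1] - p[i]) / dt if i + 1 < len(p) else 0.0
    return v


def run_mask(
    trace: BehaviorTrace, speed_threshold: float = 4.0, min_run: float = 40.0
) -> RunMask:
    """Mark long running periods: speed above threshold for >= ``min_run`` cm.

    A sample is kept when it belongs to a maximal contiguous epoch in which
    the instantaneous speed exceeds ``speed_threshold`` cm/s and the net
    distance covered by the epoch is at least ``min_run`` cm.  Teleports
    break epochs.
    """
    if speed_threshold <= 0 or min_run <= 0:
        raise ValueError("thresholds must be positive")
    v = speed_trace(trace)
    fast = v > speed_threshold
    # teleport boundaries split epochs
    fast_b = fast.copy()
    for i in np.asarray(trace.lap_starts):
        if 0 <= i < len(fast_b):
            fast_b[i] = fast_b[i]  # boundary handled by distance check below
    mask = np.zeros_like(fast)
    p = trace.position * 100.0
    edges = np.flatnonzero(np.diff(np.concatenate(([0], fast_b.view(np.int8), [0]))))
    lap_set = set(int(i) for i in np.asarray(trace.lap_starts))
    for s, e in zip(edges[::2], edges[1::2]):
        # split the epoch at teleports inside it
        cuts = sorted([i for i in lap_set if s < i < e])
        bounds = [s] + cuts + [e]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a >= 2 and (p[b - 1] - p[a]) >= min_run:
                mask[a:b] = True
    return RunMask(mask, speed_threshold, min_run)


def session_inclusion(trace: BehaviorTrace) -> bool:
    """Session quality rule: >= 20 qualifying laps in a 5- to 30-min session.

    A lap qualifies when it contains a continuous run of at least 40 cm at
    over 7 cm/s.
    """
    dur_min = trace.duration / 60.0
    if not (5.0 <= dur_min <= 30.0):
        return False
    rm = run_mask(trace, speed_threshold=7.0, min_run=40.0)
    bounds = np.concatenate(([0], np.asarray(trace.lap_starts), [len(trace.position)]))
    qualifying = sum(
        1 for a, b in zip(bounds[:-1], bounds[1:]) if np.any(rm.mask[a:b])
    )
    return qualifying >= 20


def load_behavior(
    path, sample_rate: float = SAMPLE_RATE, track_length: float = TRACK_LENGTH, delimiter=None
) -> BehaviorTrace:
    """Read a two-column (time s, position m) text file, resampled uniformly."""
    raw = np.loadtxt(path, delimiter=delimiter)
    t, p = raw[:, 0], raw[:, 1]
    tt = np.arange(t[0], t[-1], 1.0 / sample_rate)
    pp = np.interp(tt, t, p)
    return BehaviorTrace(tt - tt[0], pp, sample_rate, track_length)


def save_behavior(trace: BehaviorTrace, path) -> None:
    np.savetxt(path, np.column_stack([trace.timestamps, trace.position]), fmt="%.6f")
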