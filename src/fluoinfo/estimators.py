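"""Mutual-information estimators for spatial activity.

Implements the rate-map (Skaggs/SMGM) spatial-information metrics for spike
and fluorescence maps, the plug-in binned estimator on the joint
activity-position histogram, the Kraskov-Stogbauer-Grassberger (KSG,
algorithm 2) k-nearest-neighbor estimator, and closed-form analytic
approximations of the fluorescence metrics for Gaussian fields.

The two SMGM forms are, over N spatial bins with occupancy p_i, per-bin
activity a_i (firing rate in Hz or mean dF/F) and overall mean m = sum p_i a_i:

    bits/s  : I_s  = sum_i a_i p_i log2(a_i / m)
    bits/AP : I_AP = I_s / m

Applied to firing-rate maps these are the classical estimators; applied to
fluorescence maps the bits/s form picks up a kernel-dependent scale factor
while the bits/AP form is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .behavior import BehaviorTrace, RunMask
from .spiketrain import FrameSeries

__all__ = [
    "SpatialMaps",
    "MIEstimate",
    "spatial_maps",
    "smgm_bits_per_second",
    "smgm_bits_per_ap",
    "binned_mi",
    "ksg_mi",
    "analytic_approximations",
    "frame_positions",
]

N_BINS = 60  # 5-cm bins on the 3-m track


@dataclass
class SpatialMaps:
    """Binned occupancy and activity maps used by the SMGM estimators."""

    occupancy: np.ndarray     # probability per bin, sums to 1 over occupied bins
    activity: np.ndarray      # lambda_i (Hz) or f_i (dF/F) per bin
    occupied: np.ndarray      # boolean; bins with nonzero dwell time
    source_units: str         # "hz", "dff", or "arbitrary"

    @property
    def n_bins(self) -> int:
        return len(self.occupancy)

    @property
    def overall_mean(self) -> float:
        return float(np.sum(self.occupancy[self.occupied] * self.activity[self.occupied]))


@dataclass
class MIEstimate:
    value: float
    units: str    # bits_per_sec | bits_per_ap | dff_bits_scaled | bits_per_sample
    method: str


def frame_positions(trace: BehaviorTrace, frames: FrameSeries) -> np.ndarray:
    """Track position (m) interpolated at frame-center times."""
    return np.interp(frames.times, trace.timestamps, trace.position)


def _frame_mask(trace: BehaviorTrace, frames: FrameSeries, mask: RunMask | None) -> np.ndarray:
    if mask is None:
        return np.ones(len(frames.values), dtype=bool)
    idx = np.clip(
        np.round(frames.times * trace.sample_rate - 0.5).astype(int), 0, len(mask.mask) - 1
    )
    return mask.mask[idx]


def spatial_maps(
    activity: FrameSeries,
    trace: BehaviorTrace,
    mask: RunMask | None = None,
    n_bins: int = N_BINS,
    source_units: str = "hz",
    floor_negative: bool = True,
) -> SpatialMaps:
    """Bin run-period frames by position into occupancy and mean-activity maps.

    AP-count frames are converted to Hz (counts x frame rate); dF/F frames
    are averaged as-is.  With additive recording noise a fluorescence bin
    mean can come out negative; such bins are floored to 0 so they
    contribute nothing to the information sums (``floor_negative=False``
    disables the rule).  Unoccupied bins are flagged and excluded, with
    occupancy renormalized over the occupied ones.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    keep = _frame_mask(trace, activity, mask)
    pos = frame_positions(trace, activity)[keep]
    vals = np.asarray(activity.values, dtype=float)[keep]
    if source_units == "hz":
        vals = vals * activity.frame_rate
    bins = np.clip((pos / trace.track_length * n_bins).astype(int), 0, n_bins - 1)
    dwell = np.bincount(bins, minlength=n_bins).astype(float)
    occupied = dwell > 0
    if occupied.sum() < 2:
        raise ValueError("degenerate session: fewer than 2 occupied spatial bins")
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    act = np.zeros(n_bins)
    act[occupied] = sums[occupied] / dwell[occupied]
    if floor_negative:
        act = np.maximum(act, 0.0)
    occ = np.where(occupied, dwell / dwell.sum(), 0.0)
    return SpatialMaps(occ, act, occupied, source_units)


def smgm_bits_per_second(maps: SpatialMaps) -> MIEstimate:
    """Rate-map information in bits/s (scaled dF/F-bits for fluorescence maps).

    ``sum_i a_i p_i log2(a_i / m)`` over occupied bins; zero-activity bins
    contribute 0 by the x log x -> 0 limit.
    """
    m = maps.overall_mean
    if m <= 0.0:
        raise ValueError("overall mean activity must be positive")
    a = maps.activity[maps.occupied]
    p = maps.occupancy[maps.occupied]
    if np.any(a < 0):
        raise ValueError("negative activity bins; apply the floor rule first")
    pos = a > 0
    val = float(np.sum(a[pos] * p[pos] * np.log2(a[pos] / m)))
    units = "bits_per_sec" if maps.source_units == "hz" else "dff_bits_scaled"
    return MIEstimate(val, units, "smgm_sec")


def smgm_bits_per_ap(maps: SpatialMaps) -> MIEstimate:
    """Mean-normalized rate-map information in bits/AP (scale-free)."""
    sec = smgm_bits_per_second(maps)
    return MIEstimate(sec.value / maps.overall_mean, "bits_per_ap", "smgm_ap")


def _plugin_mi_bits(joint: np.ndarray) -> float:
    """Plug-in MI (bits/sample) of a joint count histogram."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def binned_mi(
    activity: FrameSeries | np.ndarray,
    position_bins: np.ndarray,
    activity_bins: int = 10,
    n_position_bins: int = N_BINS,
    scheme: str = "uniform",
    frame_rate: float | None = None,
) -> MIEstimate:
    """Plug-in MI from the discretized joint activity-position histogram.

    The activity trace is cut into ``activity_bins`` levels, either
    equal-width over its range (``uniform``) or equal-count quantiles
    (``occupancy``); position arrives pre-binned.  The per-sample plug-in MI
    is scaled by the frame rate to report bits/s.
    """
    if activity_bins < 2:
        raise ValueError("activity_bins must be >= 2")
    if isinstance(activity, FrameSeries):
        if frame_rate is None:
            frame_rate = activity.frame_rate
        vals = np.asarray(activity.values, dtype=float)
    else:
        vals = np.asarray(activity, dtype=float)
        if frame_rate is None:
            raise ValueError("frame_rate required for raw arrays")
    position_bins = np.asarray(position_bins)
    if np.ptp(vals) == 0.0:
        return MIEstimate(0.0, "bits_per_sec", f"binned_{scheme}")
    if scheme == "uniform":
        edges = np.linspace(vals.min(), vals.max(), activity_bins + 1)
    elif scheme == "occupancy":
        edges = np.quantile(vals, np.linspace(0.0, 1.0, activity_bins + 1))
        edges = np.unique(edges)
    else:
        raise ValueError("scheme must be 'uniform' or 'occupancy'")
    # right-closed top edge; ties at a quantile edge fall in the lower bin
    lvl = np.clip(np.searchsorted(edges, vals, side="left") - 1, 0, len(edges) - 2)
    joint = np.zeros((n_position_bins, len(edges) - 1))
    np.add.at(joint, (position_bins, lvl), 1.0)
    per_sample = _plugin_mi_bits(joint)
    return MIEstimate(per_sample * frame_rate, "bits_per_sec", f"binned_{scheme}")


def ksg_mi(
    activity: np.ndarray,
    position: np.ndarray,
    k: int = 5,
    frame_rate: float | None = None,
    jitter: float | None = 1e-10,
    seed: int | np.random.Generator = 0,
) -> MIEstimate:
    """KSG algorithm-2 k-nearest-neighbor MI estimate.

    For each sample the k-th neighbor is found in the max-norm joint space;
    the per-dimension projected extents of that neighborhood define the
    marginal counts n_x, n_y, and

        I = psi(k) - 1/k + psi(N) - < psi(n_x) + psi(n_y) >   (nats)

    is converted to bits.  Duplicate-heavy data (frame-binned counts) are
    broken by an optional uniform jitter of ``jitter`` x data range,
    deterministic given the seed.  Reported per sample, and additionally in
    bits/s when a frame rate is supplied.
    """
    x = np.asarray(activity, dtype=float).copy()
    y = np.asarray(position, dtype=float).copy()
    n = len(x)
    if n != len(y):
        raise ValueError("activity and position must have equal length")
    if k < 1 or n < k + 2:
        raise ValueError("need k >= 1 and at least k+2 samples")
    if jitter:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        x = x + rng.uniform(-1, 1, n) * jitter * max(np.ptp(x), 1e-30)
        y = y + rng.uniform(-1, 1, n) * jitter * max(np.ptp(y), 1e-30)
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    dists, idx = tree.query(pts, k=k + 1, p=np.inf)
    # projected half-extents of the k-NN neighborhood in each marginal
    eps_x = np.max(np.abs(x[idx[:, 1:]] - x[:, None]), axis=1)
    eps_y = np.max(np.abs(y[idx[:, 1:]] - y[:, None]), axis=1)
    xs = np.sort(x)
    ys = np.sort(y)
    nx = (
        np.searchsorted(xs, x + eps_x, side="right")
        - np.searchsorted(xs, x - eps_x, side="left")
        - 1
    )
    ny = (
        np.searchsorted(ys, y + eps_y, side="right")
        - np.searchsorted(ys, y - eps_y, side="left")
        - 1
    )
    nats = (
        digamma(k)
        - 1.0 / k
        + digamma(n)
        - np.mean(digamma(np.maximum(nx, 1)) + digamma(np.maximum(ny, 1)))
    )
    bits = nats / np.log(2.0)
    if frame_rate is not None:
        return MIEstimate(bits * frame_rate, "bits_per_sec", "ksg")
    return MIEstimate(bits, "bits_per_sample", "ksg")


def analytic_approximations(
    i_true: float,
    mean_rate: float = 1.0,
    v: float = 0.0643,
    tau: float = 0.2,
    amplitude: float = 0.19,
    which: str = "per_ap",
) -> MIEstimate:
    """Closed-form fluorescence-information approximations for Gaussian fields.

    With a Gaussian rate map, a single-exponential kernel of time constant
    ``tau`` (s), constant normalized running speed ``v`` (track lengths per
    second) and kernel amplitude scale ``amplitude``:

        per_sec: I ~ -A v tau rate * log(4^(-I_true/rate) + 2 pi e v^2 tau^2) / log 4
        per_ap : I ~ -log(4^(-I_true) + 2 e pi v^2 tau^2) / log 4

    At tau = 0 the per-AP form returns ``i_true`` exactly and the per-second
    form vanishes through its prefactor.
    """
    if tau < 0 or v <= 0:
        raise ValueError("tau must be >= 0 and v > 0")
    if which == "per_ap":
        val = -np.log(4.0 ** (-i_true) + 2.0 * np.e * np.pi * v**2 * tau**2) / np.log(4.0)
        return MIEstimate(float(val), "bits_per_ap", "analytic_ap")
    if which == "per_sec":
        inner = 4.0 ** (-i_true / mean_rate) + 2.0 * np.pi * np.e * v**2 * tau**2
        val = -amplitude * v * tau * mean_rate * np.log(inner) / np.log(4.0)
        return MIEstimate(float(val), "dff_bits_scaled", "analytic_sec")
    raise ValueError("which must be 'per_ap' or 'per_sec'")
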