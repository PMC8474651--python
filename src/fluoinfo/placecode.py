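"""Downstream population analyses: transients, place fields, decoding.

Significant dF/F transients are detected by comparing positive- and
negative-going excursions: because additive recording noise is symmetric
while real indicator transients are strictly positive, the rate of
negative-going events in an (amplitude, duration) class estimates the false
positive rate for the matching positive class.  Detected transients feed a
bootstrap place-field test and a Bayesian position decoder operating on
per-window counts of significant frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior import BehaviorTrace, RunMask
from .estimators import N_BINS, frame_positions, _frame_mask
from .spiketrain import FrameSeries

__all__ = [
    "TransientMask",
    "PlaceField",
    "DecodeResult",
    "detect_transients",
    "find_place_fields",
    "bayes_decode",
    "quantile_split",
]


@dataclass
class TransientMask:
    mask: np.ndarray                  # boolean per frame
    threshold_table: list             # accepted (min amplitude sigma, min duration frames)
    target_fpr: float
    analytic_fallback: bool = False


@dataclass
class PlaceField:
    start_bin: int
    end_bin: int          # inclusive
    bin_size_cm: float = 5.0

    @property
    def width(self) -> float:
        return (self.end_bin - self.start_bin + 1) * self.bin_size_cm


@dataclass
class DecodeResult:
    decoded_bin: np.ndarray
    truth_bin: np.ndarray
    abs_error: np.ndarray    # % of track per window
    window: float
    train_fraction: float
    prior_fallback: np.ndarray  # windows decoded from the prior alone

    @property
    def median_abs_error(self) -> float:
        return float(np.median(self.abs_error))


def _events(above: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of contiguous True runs; stop exclusive."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def detect_transients(
    trace: FrameSeries,
    noise_sd_estimate: float | None = None,
    target_fpr: float = 1e-4,
    amp_step: float = 0.5,
    onset_sigma: float = 2.0,
    min_events: int = 10,
) -> TransientMask:
    """Flag frames inside statistically significant positive dF/F transients.

    Candidate events are contiguous excursions beyond +/- ``onset_sigma``
    times the noise SD.  Events are classed by peak amplitude (0.5-sigma
    steps from 2 sigma) and duration (frames); a positive class is accepted
    when, cumulatively over larger amplitudes and longer durations, the
    negative-to-positive count ratio is below ``target_fpr``.  At least
    ``min_events`` positive events are required before a class can be
    accepted, so isolated noise excursions cannot certify themselves.  When
    too few negative events exist to estimate the ratio, analytic
    Gaussian-null thresholds are used instead.
    """
    x = np.asarray(trace.values, dtype=float)
    if len(x) < 1000:
        raise ValueError("need >= 1000 frames for stable negative-event statistics")
    sd = float(np.std(x)) if noise_sd_estimate is None else float(noise_sd_estimate)
    if sd == 0.0:
        return TransientMask(np.zeros(len(x), bool), [], target_fpr)

    def classify(sign: float):
        ev = _events(sign * x > onset_sigma * sd)
        amps = np.array([np.max(sign * x[s:e]) / sd for s, e in ev])
        durs = np.array([e - s for s, e in ev], dtype=int)
        return ev, amps, durs

    pos_ev, pos_amp, pos_dur = classify(+1.0)
    neg_ev, neg_amp, neg_dur = classify(-1.0)

    if len(pos_ev) == 0:
        return TransientMask(np.zeros(len(x), bool), [], target_fpr)

    accepted: list[tuple[float, int]] = []
    mask = np.zeros(len(x), dtype=bool)
    if len(neg_ev) < 10:
        # Analytic fallback: a 4.5-sigma peak lasting >= 2 frames has
        # negligible probability under white Gaussian noise.
        accepted = [(4.5, 2)]
        fallback = True
    else:
        fallback = False
        amp_grid = np.arange(onset_sigma, max(pos_amp.max(), onset_sigma) + amp_step, amp_step)
        dur_grid = np.arange(1, max(pos_dur.max(), 1) + 1)
        for a0 in amp_grid:
            for d0 in dur_grid:
                npos = int(np.sum((pos_amp >= a0) & (pos_dur >= d0)))
                nneg = int(np.sum((neg_amp >= a0) & (neg_dur >= d0)))
                if npos >= min_events and nneg / npos < target_fpr:
                    accepted.append((float(a0), int(d0)))
                    break  # longer durations at this amplitude are implied
    for s, e in pos_ev:
        amp = np.max(x[s:e]) / sd
        dur = e - s
        if any(amp >= a0 and dur >= d0 for a0, d0 in accepted):
            mask[s:e] = True
    return TransientMask(mask, accepted, target_fpr, analytic_fallback=fallback)


def _fluor_map(
    values: np.ndarray, bins: np.ndarray, n_bins: int, smooth: int = 3
) -> np.ndarray:
    dwell = np.bincount(bins, minlength=n_bins).astype(float)
    sums = np.bincount(bins, weights=values, minlength=n_bins)
    m = np.divide(sums, dwell, out=np.zeros(n_bins), where=dwell > 0)
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        m = np.convolve(m, kern, mode="same")
    return m


def find_place_fields(
    dff: FrameSeries,
    trace: BehaviorTrace,
    transients: TransientMask,
    mask: RunMask | None = None,
    n_boot: int = 1000,
    n_bins: int = N_BINS,
    seed: int | np.random.Generator = 0,
    width_bounds_cm: tuple[float, float] = (20.0, 120.0),
) -> list[PlaceField]:
    """Bootstrap place-field test on the transient-restricted intensity map.

    The boxcar-smoothed 60-bin fluorescence map (transient frames only) is
    compared against surrogate maps in which transient events keep their
    shapes but are re-placed in random order at random positions within the
    run-period frames.  Contiguous bins exceeding the 99th percentile of the
    surrogates form candidate fields, retained when 20-120 cm wide.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    keep = _frame_mask(trace, dff, mask) if mask is not None else np.ones(len(dff.values), bool)
    x = np.asarray(dff.values, dtype=float)
    tmask = transients.mask & keep
    if not tmask.any():
        return []
    pos = frame_positions(trace, dff)
    bins_all = np.clip((pos / trace.track_length * n_bins).astype(int), 0, n_bins - 1)
    run_idx = np.flatnonzero(keep)
    sig = np.where(tmask, x, 0.0)

    real = _fluor_map(sig[keep], bins_all[keep], n_bins)

    events = [(s, e) for s, e in _events(tmask)]
    segs = [x[s:e] for s, e in events]
    boot = np.empty((n_boot, n_bins))
    n_run = len(run_idx)
    for b in range(n_boot):
        surro = np.zeros(n_run)
        order = rng.permutation(len(segs))
        for j in order:
            seg = segs[j]
            if len(seg) >= n_run:
                continue
            start = rng.integers(0, n_run - len(seg))
            surro[start : start + len(seg)] = seg
        boot[b] = _fluor_map(surro, bins_all[run_idx], n_bins)
    thresh = np.percentile(boot, 99.0, axis=0)

    fields = []
    for s, e in _events(real > thresh):
        f = PlaceField(s, e - 1, bin_size_cm=trace.track_length * 100.0 / n_bins)
        if width_bounds_cm[0] <= f.width <= width_bounds_cm[1]:
            fields.append(f)
    return fields


def bayes_decode(
    population: list[FrameSeries],
    trace: BehaviorTrace,
    window: float = 0.1,
    train_fraction: float = 0.8,
    n_bins: int = N_BINS,
    mask: RunMask | None = None,
) -> DecodeResult:
    """Bayesian position decoding from significant-frame indicator series.

    Each population entry is a 0/1 per-frame series marking significant
    frames for one neuron.  Per-neuron rates of significant frames per
    spatial bin (f_ij, 1/s) are estimated on the first ``train_fraction`` of
    the session; on the held-out tail the posterior over bins for each
    ``window``-second block is

        log p(x_i | n) = log p_X(x_i) + sum_j n_j log f_ij - dt sum_j f_ij

    and the decoded bin is the argmax.  Windows in which every bin has zero
    posterior mass fall back to the occupancy-prior argmax and are flagged.
    """
    if not population:
        raise ValueError("need at least one neuron")
    frame_rate = population[0].frame_rate
    n_frames = len(population[0].values)
    pos = frame_positions(trace, population[0])
    bins = np.clip((pos / trace.track_length * n_bins).astype(int), 0, n_bins - 1)
    keep = _frame_mask(trace, population[0], mask)

    split = int(np.floor(train_fraction * n_frames))
    train_keep = keep.copy()
    train_keep[split:] = False

    dwell = np.bincount(bins[train_keep], minlength=n_bins).astype(float)
    occupied = dwell > 0
    prior = np.where(occupied, dwell / dwell.sum(), 0.0)
    f = np.zeros((n_bins, len(population)))  # f_ij, significant-frame rate (1/s)
    for j, series in enumerate(population):
        v = np.asarray(series.values, dtype=float)
        sums = np.bincount(bins[train_keep], weights=v[train_keep], minlength=n_bins)
        f[:, j] = np.divide(sums, dwell, out=np.zeros(n_bins), where=occupied) * frame_rate

    frames_per_win = max(int(round(window * frame_rate)), 1)
    test_idx = np.arange(split, n_frames)
    test_idx = test_idx[keep[split:]] if mask is not None else test_idx
    n_win = len(test_idx) // frames_per_win
    with np.errstate(divide="ignore"):
        log_prior = np.where(prior > 0, np.log(np.maximum(prior, 1e-300)), -np.inf)
        log_f = np.where(f > 0, np.log(np.maximum(f, 1e-300)), -np.inf)
    sum_f = f.sum(axis=1)
    no_rates = not f.any()  # decoder carries no rate information at all

    decoded = np.empty(n_win, dtype=int)
    truth = np.empty(n_win, dtype=int)
    fallback = np.zeros(n_win, dtype=bool)
    for w in range(n_win):
        idx = test_idx[w * frames_per_win : (w + 1) * frames_per_win]
        n_j = np.array([np.asarray(series.values)[idx].sum() for series in population])
        active = n_j > 0
        logp = log_prior - window * sum_f
        if active.any():
            logp = logp + (log_f[:, active] * n_j[active]).sum(axis=1)
        logp[~occupied] = -np.inf
        if no_rates or not np.isfinite(logp).any():
            decoded[w] = int(np.argmax(prior))
            fallback[w] = True
        else:
            decoded[w] = int(np.argmax(logp))
        truth[w] = int(np.round(np.mean(bins[idx])))
    abs_err = np.abs(decoded - truth) / n_bins * 100.0
    return DecodeResult(decoded, truth, abs_err, window, train_fraction, fallback)


def quantile_split(
    result: pd.DataFrame, metric_column: str, n_quantiles: int = 3
) -> list[pd.DataFrame]:
    """Partition neurons into equal-count groups by a metric, ties stable.

    Returns the groups lowest to highest; a rank-based split, so any
    strictly monotone relabeling of the metric leaves the partition
    unchanged.
    """
    if len(result) < n_quantiles:
        raise ValueError("need at least one neuron per quantile")
    order = np.argsort(result[metric_column].to_numpy(), kind="stable")
    parts = np.array_split(order, n_quantiles)
    return [result.iloc[np.sort(p)] for p in parts]
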