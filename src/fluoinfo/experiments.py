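"""Library-scale simulation experiments quantifying estimator bias.

The central object is the neuron library: for each mock neuron a target
(mean rate, information) pair is drawn, a spline rate map is built carrying
exactly that information, a synthetic track session of 3-60 minutes is
assembled, Poisson spikes are generated and turned into a noisy dF/F trace,
and every estimator is evaluated against the known ground truth.  Sweep
helpers vary kernel height, kernel width, and spatial bin count, and error
summaries report the linear and saturating-exponential fits used to
characterize each estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import chi2

from . import behavior as bhv
from . import estimators as est
from . import fluorescence as fluo
from . import ratemaps as rm
from . import spiketrain as spk

__all__ = [
    "ErrorSummary",
    "make_behavior_pool",
    "simulate_neuron",
    "run_library",
    "summarize_errors",
    "kernel_height_sweep",
    "kernel_width_sweep",
    "density_sweep",
    "bin_count_sweep",
]


@dataclass
class ErrorSummary:
    """Error statistics of one estimate column against ground truth."""

    n: int
    mean_error: float
    sd_error: float
    mean_abs_error: float
    mean_pct_error: float
    sd_pct_error: float
    mean_abs_pct_error: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    satexp_amplitude: float = np.nan   # y = A (1 - exp(-x / B))
    satexp_rate: float = np.nan        # B
    lrt_chi2: float = np.nan
    lrt_p: float = np.nan
    flags: list = field(default_factory=list)


def make_behavior_pool(
    n_sessions: int = 48,
    session_minutes: float = 10.0,
    seed: int | np.random.Generator = 0,
    **synth_kwargs,
) -> list[bhv.BehaviorTrace]:
    """Generate a reusable pool of synthetic track sessions.

    Mirrors drawing sessions from a fixed recorded-behavior library: each
    neuron's session is assembled by concatenating randomly chosen pool
    entries and truncating to its own duration.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return [
        bhv.synth_behavior(session_minutes * 60.0, seed=rng, **synth_kwargs)
        for _ in range(n_sessions)
    ]


def _draw_session(
    pool: list[bhv.BehaviorTrace], minutes: float, rng: np.random.Generator
) -> bhv.BehaviorTrace:
    target = minutes * 60.0
    picks, total = [], 0.0
    while total < target:
        tr = pool[rng.integers(len(pool))]
        picks.append(tr)
        total += tr.duration
    return bhv.assemble_session(picks, target)


def simulate_neuron(
    map_: rm.RateMap,
    trace: bhv.BehaviorTrace,
    kernel: fluo.Kernel,
    rng: np.random.Generator,
    noise_sd: float = fluo.NOISE_SD,
    n_bins: int = est.N_BINS,
    include_binned: bool = False,
    include_ksg: bool = False,
    nonlinearity: bool = False,
    apply_run_mask: bool = False,
    return_frames: bool = False,
) -> dict:
    """Run the full pipeline for one neuron and return all estimates.

    Maps are computed over all frames by default: the intensity-map mean
    then matches the whole-session normalization of the conditional
    intensity, which is what makes the spike metrics recover ground truth
    nearly unbiased.  ``apply_run_mask=True`` restricts the maps to
    long-running periods instead, as done for real recordings.
    """
    cif = spk.build_cif(map_, trace)
    train = spk.generate_spikes(cif, seed=rng)
    frames = spk.bin_to_frames(train)
    dff = fluo.synth_fluorescence(train, kernel, noise_sd=noise_sd, seed=rng)
    if nonlinearity:
        dff = fluo.apply_nonlinearity(dff)
    mask = bhv.run_mask(trace) if apply_run_mask else None
    maps_spk = est.spatial_maps(frames, trace, mask, n_bins=n_bins, source_units="hz")
    maps_dff = est.spatial_maps(dff, trace, mask, n_bins=n_bins, source_units="dff")
    i_ap = map_.achieved_info_ap
    out = {
        "i_ap_true": i_ap,
        "i_s_true": i_ap * map_.mean_rate,
        "mean_rate": map_.mean_rate,
        "duration_s": trace.duration,
        "lap_count": trace.n_laps,
        "n_spikes": train.n_spikes,
        "spike_smgm_s": est.smgm_bits_per_second(maps_spk).value,
        "spike_smgm_ap": est.smgm_bits_per_ap(maps_spk).value,
        "fluo_smgm_s": est.smgm_bits_per_second(maps_dff).value,
        "fluo_smgm_ap": est.smgm_bits_per_ap(maps_dff).value,
    }
    if include_binned or include_ksg:
        keep = est._frame_mask(trace, dff, mask)
        pos = est.frame_positions(trace, dff)[keep]
        pos_bins = np.clip(
            (pos / trace.track_length * n_bins).astype(int), 0, n_bins - 1
        )
        if include_binned:
            vals = np.asarray(dff.values)[keep]
            for scheme in ("uniform", "occupancy"):
                out[f"fluo_binned_{scheme}"] = est.binned_mi(
                    vals, pos_bins, scheme=scheme, n_position_bins=n_bins,
                    frame_rate=dff.frame_rate,
                ).value
        if include_ksg:
            out["fluo_ksg"] = est.ksg_mi(
                np.asarray(dff.values)[keep], pos, frame_rate=dff.frame_rate, seed=rng
            ).value
    if return_frames:
        out["_frames"] = frames
        out["_dff"] = dff
        out["_trace"] = trace
        out["_mask"] = mask
    return out


def run_library(
    n_neurons: int,
    indicator: str | fluo.Kernel = "gCaMP6f",
    session_minutes_range: tuple[float, float] = (3.0, 60.0),
    seed: int = 0,
    noise_sd: float = fluo.NOISE_SD,
    behavior_pool: list[bhv.BehaviorTrace] | None = None,
    include_binned: bool = False,
    include_ksg: bool = False,
    nonlinearity: bool = False,
) -> pd.DataFrame:
    """Simulate a neuron library and estimate information every way.

    Fully reproducible from the master seed: targets, rate maps, sessions,
    spikes and noise all derive from per-neuron child seeds, so any
    execution order yields the same table.  Neurons whose rate-map
    optimization fails are returned as flagged rows rather than aborting.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    kernel = fluo.get_kernel(indicator) if isinstance(indicator, str) else indicator
    master = np.random.SeedSequence(seed)
    pool_ss, targets_ss, *neuron_ss = master.spawn(n_neurons + 2)
    if behavior_pool is None:
        behavior_pool = make_behavior_pool(seed=np.random.default_rng(pool_ss))
    targets = rm.sample_targets(n_neurons, seed=np.random.default_rng(targets_ss))
    rows = []
    for i, (tgt, ss) in enumerate(zip(targets, neuron_ss)):
        rng = np.random.default_rng(ss)
        minutes = rng.uniform(*session_minutes_range)
        trace = _draw_session(behavior_pool, minutes, rng)
        row = {
            "neuron_id": i,
            "target_i_ap": tgt.i_ap,
            "target_domain": tgt.sampled_domain,
            "seed": int(ss.entropy) % (2**31),
            "failed": False,
        }
        try:
            map_ = rm.optimize_ratemap(tgt.i_ap, seed=rng)
            map_.mean_rate = tgt.mean_rate
            row.update(
                simulate_neuron(
                    map_, trace, kernel, rng,
                    noise_sd=noise_sd,
                    include_binned=include_binned,
                    include_ksg=include_ksg,
                    nonlinearity=nonlinearity,
                )
            )
        except (rm.ConvergenceError, ValueError) as exc:
            row["failed"] = True
            row["failure"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _satexp(x, A, B):
    return A * (1.0 - np.exp(-x / np.maximum(B, 1e-12)))


def summarize_errors(
    result: pd.DataFrame, estimate_column: str, truth_column: str
) -> ErrorSummary:
    """Error statistics, linear and saturating-exponential fits, and the LRT.

    Percent errors use the ground truth as denominator; rows with zero truth
    are excluded from percentage statistics but kept in native-unit ones.
    The likelihood-ratio test compares Gaussian-residual likelihoods of the
    saturating-exponential fit ``y = A (1 - exp(-x/B))`` against the linear
    fit, chi-square with 1 df.
    """
    df = result
    if "failed" in df.columns:
        df = df[~df["failed"].astype(bool)]
    df = df[[estimate_column, truth_column]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 rows to summarize")
    estv = df[estimate_column].to_numpy(dtype=float)
    tru = df[truth_column].to_numpy(dtype=float)
    err = estv - tru
    nz = tru != 0.0
    pct = 100.0 * err[nz] / tru[nz]
    flags = []

    n = len(tru)
    slope = slope_se = intercept = intercept_se = r2 = np.nan
    if np.std(tru) > 0:
        X = np.column_stack([np.ones(n), tru])
        beta, res_ss, *_ = np.linalg.lstsq(X, estv, rcond=None)
        pred = X @ beta
        sse_lin = float(np.sum((estv - pred) ** 2))
        tot = float(np.sum((estv - estv.mean()) ** 2))
        r2 = 1.0 - sse_lin / tot if tot > 0 else np.nan
        dof = max(n - 2, 1)
        s2 = sse_lin / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        intercept, slope = beta
        intercept_se, slope_se = np.sqrt(np.diag(cov))
    else:
        flags.append("degenerate-truth-variance")
        sse_lin = np.nan

    A = B = lrt = lrt_p = np.nan
    try:
        import warnings

        p0 = [max(estv.max(), 1e-6), max(tru.max() / 2.0, 1e-6)]
        with warnings.catch_warnings():
            # near-linear data makes the exponential's covariance singular
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_satexp, tru, estv, p0=p0, maxfev=10_000)
        A, B = popt
        sse_exp = float(np.sum((estv - _satexp(tru, A, B)) ** 2))
        if np.isfinite(sse_lin) and sse_exp > 0:
            lrt = n * np.log(sse_lin / sse_exp)
            lrt_p = float(chi2.sf(max(lrt, 0.0), df=1))
    except RuntimeError:
        flags.append("satexp-fit-failed")

    return ErrorSummary(
        n=n,
        mean_error=float(err.mean()),
        sd_error=float(err.std(ddof=1)),
        mean_abs_error=float(np.abs(err).mean()),
        mean_pct_error=float(pct.mean()) if len(pct) else np.nan,
        sd_pct_error=float(pct.std(ddof=1)) if len(pct) > 1 else np.nan,
        mean_abs_pct_error=float(np.abs(pct).mean()) if len(pct) else np.nan,
        slope=float(slope),
        slope_se=float(slope_se),
        intercept=float(intercept),
        intercept_se=float(intercept_se),
        r_squared=float(r2),
        satexp_amplitude=float(A),
        satexp_rate=float(B),
        lrt_chi2=float(lrt),
        lrt_p=float(lrt_p),
        flags=flags,
    )


def kernel_height_sweep(
    n: int,
    heights: tuple[float, float] = (0.0, 3.0),
    base_kernel: str | fluo.Kernel = "gCaMP6f",
    seed: int = 0,
    session_minutes_range: tuple[float, float] = (3.0, 60.0),
    noise_sd: float = fluo.NOISE_SD,
    behavior_pool: list[bhv.BehaviorTrace] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Vary kernel height at fixed shape and regress percent error on height.

    Returns the per-trace table and the linear fit of the fluorescence
    bits/s percent error versus height (slope, intercept, standard errors),
    plus the same fit for the scale-free bits/AP metric, where no height
    dependence is expected.
    """
    base = fluo.get_kernel(base_kernel) if isinstance(base_kernel, str) else base_kernel
    if not (0.0 <= heights[0] and heights[1] <= 3.0):
        raise ValueError("heights must lie within [0, 3] dF/F")
    master = np.random.SeedSequence(seed)
    pool_ss, targets_ss, *neuron_ss = master.spawn(n + 2)
    if behavior_pool is None:
        behavior_pool = make_behavior_pool(seed=np.random.default_rng(pool_ss))
    targets = rm.sample_targets(n, seed=np.random.default_rng(targets_ss))
    rows = []
    for i, (tgt, ss) in enumerate(zip(targets, neuron_ss)):
        rng = np.random.default_rng(ss)
        h = rng.uniform(*heights)
        kernel = fluo.Kernel(base.a, base.b, h, base.rise, base.half_fall, name="height-sweep")
        minutes = rng.uniform(*session_minutes_range)
        trace = _draw_session(behavior_pool, minutes, rng)
        map_ = rm.optimize_ratemap(tgt.i_ap, seed=rng)
        map_.mean_rate = tgt.mean_rate
        r = simulate_neuron(map_, trace, kernel, rng, noise_sd=noise_sd)
        rows.append(
            {
                "neuron_id": i,
                "height": h,
                **r,
                "pct_err_s": 100.0 * (r["fluo_smgm_s"] - r["i_s_true"]) / r["i_s_true"]
                if r["i_s_true"] > 0
                else np.nan,
                "pct_err_ap": 100.0 * (r["fluo_smgm_ap"] - r["i_ap_true"]) / r["i_ap_true"]
                if r["i_ap_true"] > 0
                else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    fits = {}
    for col in ("pct_err_s", "pct_err_ap"):
        sub = table.dropna(subset=[col])
        fits[col] = summarize_errors(
            sub.rename(columns={col: "y", "height": "x"}), "y", "x"
        )
    return table, fits


def kernel_width_sweep(
    n: int,
    seed: int = 0,
    height: float = 0.19,
    session_minutes_range: tuple[float, float] = (3.0, 60.0),
    noise_sd: float = fluo.NOISE_SD,
    behavior_pool: list[bhv.BehaviorTrace] | None = None,
) -> pd.DataFrame:
    """Vary kernel width at fixed height; tabulate percent error per trace.

    Width targets are drawn on 0.01-10 s, rise on 0.001-1 s and half-fall
    between the rise and 2 s; (a, b) are fitted to the three targets
    jointly.
    """
    master = np.random.SeedSequence(seed)
    pool_ss, targets_ss, *neuron_ss = master.spawn(n + 2)
    if behavior_pool is None:
        behavior_pool = make_behavior_pool(seed=np.random.default_rng(pool_ss))
    targets = rm.sample_targets(n, seed=np.random.default_rng(targets_ss))
    rows = []
    for i, (tgt, ss) in enumerate(zip(targets, neuron_ss)):
        rng = np.random.default_rng(ss)
        w = rng.uniform(0.01, 10.0)
        rise = rng.uniform(0.001, 1.0)
        fall = rng.uniform(rise, 2.0)
        kernel = fluo.make_sweep_kernel(w, rise, fall, height=height)
        minutes = rng.uniform(*session_minutes_range)
        trace = _draw_session(behavior_pool, minutes, rng)
        map_ = rm.optimize_ratemap(tgt.i_ap, seed=rng)
        map_.mean_rate = tgt.mean_rate
        r = simulate_neuron(map_, trace, kernel, rng, noise_sd=noise_sd)
        rows.append(
            {
                "neuron_id": i,
                "target_width": w,
                "width": kernel.width,
                **r,
                "pct_err_s": 100.0 * (r["fluo_smgm_s"] - r["i_s_true"]) / r["i_s_true"]
                if r["i_s_true"] > 0
                else np.nan,
                "pct_err_ap": 100.0 * (r["fluo_smgm_ap"] - r["i_ap_true"]) / r["i_ap_true"]
                if r["i_ap_true"] > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def density_sweep(
    result: pd.DataFrame,
    rate_edges: np.ndarray | None = None,
    lap_edges: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Mean and absolute error binned by mean firing rate and by lap count."""
    df = result[~result.get("failed", pd.Series(False, index=result.index)).astype(bool)]
    if rate_edges is None:
        rate_edges = np.array([0.1, 0.3, 0.6, 1.0, 3.0, 10.0, 30.0])
    if lap_edges is None:
        lap_edges = np.array([0, 11, 25, 50, 100, 200, 1000])
    pairs = [
        ("spike_smgm_s", "i_s_true"),
        ("spike_smgm_ap", "i_ap_true"),
        ("fluo_smgm_s", "i_s_true"),
        ("fluo_smgm_ap", "i_ap_true"),
    ]
    out = {}
    for by, edges in (("mean_rate", rate_edges), ("lap_count", lap_edges)):
        grp = pd.cut(df[by], edges)
        rows = []
        for interval, sub in df.groupby(grp, observed=True):
            row = {"bin": interval, "n": len(sub)}
            for col, truth in pairs:
                t = sub[truth].to_numpy()
                e = sub[col].to_numpy() - t
                nzl = t != 0
                row[f"{col}_mean_pct"] = (
                    float((100 * e[nzl] / t[nzl]).mean()) if nzl.any() else np.nan
                )
                row[f"{col}_mean_abs_pct"] = (
                    float(np.abs(100 * e[nzl] / t[nzl]).mean()) if nzl.any() else np.nan
                )
            rows.append(row)
        out[by] = pd.DataFrame(rows)
    return out


def bin_count_sweep(
    n: int,
    bins: tuple[int, ...] = (2, 4, 8, 15, 30, 60),
    seed: int = 0,
    indicator: str | fluo.Kernel = "gCaMP6f",
    session_minutes_range: tuple[float, float] = (3.0, 60.0),
    noise_sd: float = fluo.NOISE_SD,
    behavior_pool: list[bhv.BehaviorTrace] | None = None,
) -> pd.DataFrame:
    """Recompute the fluorescence metrics over a range of spatial bin counts.

    Each simulated session is binned at every requested count, so the error
    surface over (ground truth, bin count) comes from the same underlying
    traces.
    """
    kernel = fluo.get_kernel(indicator) if isinstance(indicator, str) else indicator
    master = np.random.SeedSequence(seed)
    pool_ss, targets_ss, *neuron_ss = master.spawn(n + 2)
    if behavior_pool is None:
        behavior_pool = make_behavior_pool(seed=np.random.default_rng(pool_ss))
    targets = rm.sample_targets(n, seed=np.random.default_rng(targets_ss))
    rows = []
    for i, (tgt, ss) in enumerate(zip(targets, neuron_ss)):
        rng = np.random.default_rng(ss)
        minutes = rng.uniform(*session_minutes_range)
        trace = _draw_session(behavior_pool, minutes, rng)
        map_ = rm.optimize_ratemap(tgt.i_ap, seed=rng)
        map_.mean_rate = tgt.mean_rate
        cif = spk.build_cif(map_, trace)
        train = spk.generate_spikes(cif, seed=rng)
        dff = fluo.synth_fluorescence(train, kernel, noise_sd=noise_sd, seed=rng)
        mask = None
        for nb in bins:
            maps = est.spatial_maps(dff, trace, mask, n_bins=nb, source_units="dff")
            i_s = est.smgm_bits_per_second(maps).value
            i_ap = est.smgm_bits_per_ap(maps).value
            truth_ap = map_.achieved_info_ap
            truth_s = truth_ap * map_.mean_rate
            rows.append(
                {
                    "neuron_id": i,
                    "n_bins": nb,
                    "i_ap_true": truth_ap,
                    "i_s_true": truth_s,
                    "fluo_smgm_s": i_s,
                    "fluo_smgm_ap": i_ap,
                    "pct_err_s": 100.0 * (i_s - truth_s) / truth_s if truth_s > 0 else np.nan,
                    "pct_err_ap": 100.0 * (i_ap - truth_ap) / truth_ap
                    if truth_ap > 0
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
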