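# Methods

## Ground-truth rate maps

A mock neuron's spatial tuning is a continuous normalized rate profile
p(x) = λ/λ̄(x) on the unit track with ∫p = 1. Its information content in
bits per action potential is the differential integral
I_AP = ∫ p log₂ p dx, evaluated by composite trapezoid on a 10,001-point
uniform grid (the same grid used for normalization; the 0·log 0 limit is
taken as 0). Profiles are exponentiated natural cubic splines through five
nodes — two anchored at the track ends, three interior with random
positions — which guarantees positivity and produces the single- and
multi-peaked fields seen in hippocampal data.

**Hitting a target exactly.** Rather than moving all node coordinates with
a general constrained optimizer, we exploit a monotonicity: scaling the
spline's log-rate values by a gain β ≥ 0 gives a profile ∝ exp(β·s(x))
whose information is 0 at β = 0 and strictly increasing in β. A bracketed
Brent root-find on β therefore drives the achieved information onto any
target in [0, 6] bits/AP deterministically; achieved errors are at solver
precision (~1e-12 bits/AP, orders of magnitude below the 1.5e-7 bits/AP
mean-absolute-error requirement we test against). Shape diversity comes
from each neuron's random node geometry; if a pathologically flat draw
cannot reach the target within the allowed gain range, a fresh random
spline is tried (a retry budget guards the loop; exceeding it raises a
convergence error carrying the best achieved value).

**Target sampling.** Library targets are drawn per neuron: with probability
0.5 the bits/AP domain is used (I_AP ~ U[0,6], λ̄ ~ U[0.1,30] Hz), otherwise
the bits/s domain (I_AP ~ U[0,6], I_s ~ U[0,24] bits/s, λ̄ = I_s/I_AP).
Draws are rejected until all three bounds hold jointly — λ̄ ∈ [0.1, 30] Hz,
I_AP ∈ [0, 6], I_s ∈ [0, 24] — which makes the realized information
distribution non-uniform by design. The 50/50 domain split is our choice;
only the sampling procedure, not the split, is pinned down externally.
Enforcing the joint I_s ≤ 24 bound matters: without it, high-rate
ultra-narrow fields (I_s up to 180 bits/s) dominate the regression and
visibly flatten the recovery slope.

Gaussian rate maps (for comparison with the closed-form approximations) use
σ = exp(½(−1 − 2 I ln2 − ln 2π)), the width at which a unit-mass Gaussian
has differential information I bits on an unbounded domain. Track-edge
truncation is flagged when more than 1% of the mass falls outside.

## Behavior

The synthetic virtual-track generator emulates head-fixed running on a 3-m
track with an end-of-track reward: forward-only motion whose speed follows
an Ornstein–Uhlenbeck process (mean 19.3 cm/s, relaxation ~2 s, stationary
SD 20% of the mean, clipped at 0), Poisson-arriving pauses (default
0.02 s⁻¹, exponential mean 2 s), and a 1.5-s freeze at the track end before
teleporting to 0. Sampling is 50 Hz. A library session concatenates random
draws from a 48-session pool (10 min each) and truncates to a per-neuron
duration ~ U[3, 60] min, mirroring how real recorded sessions are
concatenated into long mock sessions.

What the generator does **not** emulate: within-lap speed profiles tied to
track landmarks, licking/reward anticipation slowdowns, lap-to-lap
behavioral drift, and bidirectional running. Estimator-bias results that
depend only on occupancy non-uniformity and session length transfer well;
results hinging on fine behavioral autocorrelation should be re-checked
against real behavior files (`behavior.load_behavior` accepts two-column
time/position text).

Speed is a centered finite difference with teleport samples excluded (one
-3 m jump per lap would otherwise leak into the estimate). Run periods are
maximal epochs with speed > 4 cm/s covering ≥ 40 cm net; session inclusion
additionally demands ≥ 20 laps each containing a ≥ 40-cm run at > 7 cm/s
within a 5–30-min session.

## Spikes and fluorescence

The conditional intensity is the profile evaluated along the interpolated
trajectory at 1 kHz, rescaled so its session average equals λ̄ *exactly*
(the estimators' reference point). Spike counts are Poisson per 1-ms bin
with times at bin centers; imaging frames are half-open 1/30-s intervals,
so spike counts are conserved exactly.

Indicator kernels are peak-normalized double exponentials
g(t) = (e^{−at} − e^{−bt})/peak with (a, b) fitted so g peaks at the
published rise time and decays to 50% after the published half-fall time
(two conditions, two unknowns; residual ≈ 0). The kernel *width* is the
period at which the mean-normalized transfer magnitude
|H(f)| = ab/√((a²+ω²)(b²+ω²)) drops to 0.5, closed-form
ω² = (−a²−b² + √(a⁴+14a²b²+b⁴))/2. The label "−3 dB" sometimes attached to
this criterion would strictly mean |H|² = 0.5, which yields different
numbers; we implement the |H| = 0.5 reading, which reproduces the published
2.54 s (gCaMP6s) and 0.52 s (iGluSnfR-A184S) widths, and note the
discrepancy rather than resolving it. For shape sweeps, (width, rise,
half-fall) targets are drawn independently and are generally not exactly
realizable (a half-fall below ~1.3× the rise is infeasible for this
family); (a, b) then minimize the summed squared error to the three targets
and the achieved values are recorded.

ΔF/F synthesis convolves the 1-kHz spike raster with height × g(t)
(truncated where g < 1e-4 of peak), samples at frame centers, and adds
i.i.d. Gaussian noise of SD 0.15 ΔF/F per frame. Convolving the 30-Hz
frame counts instead is available as a switch
(`convolve_at_frame_rate=True`) and changes results negligibly for the
kernels considered. A saturating log-sigmoid nonlinearity
(y = sign(x)·6.264/(1 + e^{−3.251 log₁₀|x|})) can be applied elementwise to
model sublinear transient summation.

## Estimators

Spatial maps bin frames by position (60 five-cm bins by default): occupancy
is the normalized dwell count, activity the per-bin mean (counts × frame
rate for Hz; raw for ΔF/F). Unoccupied bins are excluded and occupancy
renormalized. Fluorescence bin means can be negative under additive noise;
they are floored to 0 so the x log x → 0 convention applies (the floor is
switchable). The SMGM sums run over occupied bins with zero-activity bins
contributing 0; bits/AP is bits/s divided by the overall mean, making it
invariant to any positive rescaling of the activity map — the mechanism
behind its insensitivity to kernel height.

**Library analyses use all frames, not run-masked frames.** The conditional
intensity is normalized over the entire session, so restricting maps to
run periods shifts the reference mean (reward-stop frames are removed
where the neuron's rate is whatever the profile says at the track end) and
adds a neuron-dependent ~±10% bias to the bits/s metric. Whole-session
maps recover ground truth nearly unbiased (slope ≈ 0.97), which is the
regime the recovery statistics describe. The run mask remains the default
for the real-data place-field/decoding path, where it belongs.

The binned estimator discretizes activity into 10 levels (equal-width or
equal-count; quantile ties go to the lower bin), forms the joint histogram
against the 60 position bins, computes plug-in MI in bits/sample, and
multiplies by the frame rate to report bits/s. The KSG estimator is
Kraskov's algorithm 2: max-norm k-NN balls (k = 5), per-dimension projected
extents, marginal counts via sorted searches, ψ(k) − 1/k + ψ(N) −
⟨ψ(n_x) + ψ(n_y)⟩ in nats, converted to bits; duplicates are broken by a
seeded uniform jitter of 1e-10 × range. The per-sample → per-second
conversion (× frame rate) is a convention: absolute binned/KSG magnitudes
on 30-Hz data depend on it, and comparisons against bits/s ground truth
inherit that convention.

Closed-form approximations for Gaussian fields and single-exponential
kernels are provided as printed (per-AP form exact at τ = 0; per-second
form carries an explicit amplitude-scale parameter A, exposed as an
argument since its value is a free scale).

## Library experiments

`run_library` derives every neuron's target, rate map, session, spikes, and
noise from per-neuron child seeds of one master seed, so tables are pure
functions of (config, seed) and independent of execution order. Failures
surface as flagged rows. Error summaries report native-unit and percent
errors (rows with zero truth excluded from percentages), the OLS fit with
standard errors, a saturating-exponential fit y = A(1 − e^{−x/B}), and a
Gaussian-residual likelihood-ratio statistic (χ², 1 df) comparing the two.
Percent errors always use the ground truth in the truth column's units as
denominator, including for the unit-changing fluorescence bits/s metric.

Problem sizes: the acceptance-scale library uses 1000 neurons and the
height sweep 500 traces, both with sessions drawn from the same 3–60-min
scheme; these sizes put the standard errors of the summary statistics well
below the tolerances tested while keeping a full run in minutes on one
CPU. KSG and binned estimators are opt-in per library run
(`include_ksg`, `include_binned`) since KSG's k-NN queries on ~10⁵-frame
sessions dominate runtime at library scale.

Bin-level "average percent error" in the low-truth tail deserves care: the
per-neuron percentage diverges as truth → 0 (the plug-in estimator's
positive bias divided by a vanishing denominator), so binned summaries of
the fluorescence bits/AP error report 100·|mean(est − truth)|/mean(truth)
per 0.5-bits/AP bin — a ratio of means, finite and stable — rather than a
mean of ratios.

## Transients, place fields, decoding

Significant-transient detection exploits noise symmetry: negative-going
excursions estimate the false-positive rate of matching positive classes.
Events are excursions beyond ±2σ, classed by peak amplitude (0.5σ steps)
and duration (frames); a class is accepted when, cumulatively, negative
events / positive events < 1e-4 **and** at least 10 positive events
support the estimate (without the support requirement, isolated noise
peaks certify themselves). Traces with fewer than 10 negative events fall
back to an analytic Gaussian-null threshold (≥ 4.5σ for ≥ 2 frames) with a
flag.

Place fields: the 60-bin transient-restricted fluorescence map (3-bin
boxcar smoothed) is compared against 1000 surrogates in which transient
events keep their shapes but are permuted in order and re-placed at random
run-period positions; contiguous bins above the surrogates' 99th
percentile form candidates, kept when 20–120 cm wide. The surrogate
scheme preserves event count and durations; the exact interval
distribution of the original histogram-based procedure is not specified
anywhere we could pin down, so uniform random placement is used.

The Bayesian decoder estimates per-neuron significant-frame rates f_ij per
spatial bin on the first 80% of the session and, per 0.1-s window (n_j ∈
{0..3} significant frames at 30 Hz), evaluates
log p(x_i|n) = log p_X(x_i) + Σ_j n_j log f_ij − Δt Σ_j f_ij in the log
domain; the decoded bin is the argmax and the error is |decoded − true| as
% of track with no wraparound. Windows with no finite posterior (or a
population with no rate structure at all) fall back to the occupancy-prior
argmax and are flagged. Quantile splits are rank-based with stable ties.

## Numerical notes and limitations

- All integrals share the 10,001-point trapezoid grid; normalization and
  information agree to ~1e-8 against 10× denser grids and Monte-Carlo.
- Spline evaluation subtracts the grid log-rate maximum before
  exponentiating, so extreme gains cannot overflow.
- Poisson bins at 1 kHz permit multi-spike bins; spike placement at bin
  centers is sub-frame accurate for 30-Hz binning.
- The simulation ground truth itself assumes inhomogeneous-Poisson firing;
  biases attributable to non-Poisson real spiking (bursting, hysteresis)
  are out of scope here.
- Deconvolution-based estimation is intentionally not implemented; the
  estimators operate on spikes or on fluorescence directly.
- Synthetic behavior matches first-order statistics (speed, lap rate,
  pause structure) of real virtual-track sessions but not their full
  autocorrelation; quantitative recovery numbers at the third significant
  figure will differ from runs driven by real behavior recordings.
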