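# Methods

## Sensitized-emission quantification

A FRET timepoint consists of three channels {S_DD, S_DA, S_AA}
(donor-excited donor emission, donor-excited acceptor emission, acceptor
direct excitation). Cross-talk correction uses the bleed-through factor
α = S_DA/S_DD of a donor-only control and the cross-excitation factor
δ = S_DA/S_AA of an acceptor-only control; the brightness/collection
factor γ is never estimated internally — it derives from fluorophore
spectra or dedicated control experiments and enters as a required input
(default 1.0). Direct acceptor excitation is assumed not to produce donor
emission. All intensities are background-corrected before they reach
these operations (see the time-lapse section).

The sensitized emission F_c = S_DA − α·S_DD − δ·S_AA can go negative
under noise. The raw value is preserved everywhere it feeds fits or the
unmixing algebra, so noise propagates without bias; the user-facing FRET
efficiency Θ = 1/(γ·S_DD/F_c + 1) is clipped to [0, 1] at the metrics
boundary with a per-sample flag.

S_AA is acquired at a reduced cadence because it changes only through
photodestruction or large structural rearrangements. Missing S_AA
timepoints are filled by linear interpolation between measured frames,
with nearest-value extrapolation at the ends.

## Photochromism and calibration

Off-switching light leaves a fraction ρ of the original fluorescence:
ρ_D in the donor channel, ρ_A in the acceptor channel (computed from F_c
when correction factors are available, from raw S_DA otherwise; the mode
is recorded and must be used consistently). Energy transfer competes
with off-switching, so ρ rises with Θ. For a single species with an
intrinsic off-switching quantum yield the dependence is ρ(Θ) = ρ₀^(1−Θ),
which satisfies ρ(0) = ρ₀, ρ(1) = 1 and is strictly increasing for
ρ₀ < 1; in that regime ρ_D = ρ_A because acceptor emission is
proportional to the donor on-state population.

Biosensors interconvert between active and inactive conformations and
cyan donors show multi-exponential photophysics, so the ρ(Θ) dependence
is in general measured empirically and fitted with either a straight
line or a double exponential. Fits use orthogonal distance regression
(ODRPACK) because the abscissa is itself a measured FRET metric; equal
x/y error scales are assumed since no per-point uncertainties are
available. The double exponential is parameterized as
a₁·exp(−k₁Θ) + a₂·exp(−k₂Θ) with a₁, a₂ ≥ 0 (enforced by fitting log
amplitudes) and unconstrained rates, covering both increasing and
decreasing empirical curves; the fit uses five deterministic multi-starts
and keeps the lowest-residual solution. Calibrations may be expressed
against Θ or against the (sensitized) emission ratio; the abscissa is
stored in the model and the unmixing loop iterates on whichever metric
the calibration uses. The valid range is the convex hull of the fitted
abscissa values; evaluation outside it clamps to the nearest endpoint
with a flag. Ratios slightly above 1 are tolerated up to 1.05 as noise
and flagged beyond that.

## Unmixing

With all four photoswitching ratios known, the two-pair system is linear
and solved exactly per channel — no least squares — so the recovered
per-pair components always sum to the measured mixed signal to machine
precision. When correction factors carry nonzero α or δ, the mixed
signals are first corrected to F_c (the correction is linear, so it
commutes with the per-pair sum) and the acceptor channel is unmixed in
sensitized-emission units; the result records which mode was used.

The ratios depend on the unknown efficiencies, so the solver iterates:
evaluate each pair's donor and acceptor calibration at the current
metric, solve, recompute the metric from the recovered signals, repeat.
Numerical choices:

- initial guess: midpoint of each calibration's valid range; time series
  warm-start each timepoint from the previous solution;
- convergence when the largest metric change drops below 1e−6, with a
  100-iteration cap; non-convergence is flagged in the result, not
  raised;
- oscillating updates (sign alternation between consecutive steps) are
  damped by a factor 0.5;
- Θ is capped at 0.95 inside the loop so the efficiency-to-signal
  inversion stays finite;
- |ρ₁ − ρ₂| < 0.02 in either channel raises an unresolvable-pairs error
  naming the channel: below that contrast the solution is
  noise-dominated;
- negative recovered components (possible under noise) are preserved in
  the stored solution — keeping the conservation property exact — and
  clipped to zero only where they enter the efficiency update, with a
  per-pair flag.

A pair with a dark (non-fluorescent) acceptor is supported by forcing
its acceptor-channel contribution to zero; its efficiency is not
observable from sensitized emission and is reported as NaN.

The n-pair extension solves an n×n system per channel from one on
acquisition plus n−1 progressively off-switched reads. The mixing
matrix's condition number is reported and capped at 1e3 (roughly
matching the two-pair contrast threshold at typical ρ values, but
permissive).

## Simulation study

The generator emulates the validation conditions: two spectrally
indistinguishable pairs, one photochromic donor (ρ₀ = 0.3 by default — a
value readily achievable with photochromic fluorescent proteins) and one
photostatic (ρ₀ = 1.0), efficiencies drawn uniformly from [0, 0.6],
brightness given as the photon count N the on acquisition would collect
at zero FRET. FRET moves γ-scaled photons into the acceptor channel
(E[S_DD,on] = N(1−Θ), E[S_DA,on] = γNΘ), a bookkeeping that conserves
total photons at γ = 1; off-state expectations scale by ρ₀^(1−Θ) per
pair in both channels. Each observed channel value is one independent
Poisson draw around the summed expectations — photon shot noise only, no
camera read noise, gain, or dark current — and α = δ = 0. An optional
extra-reads parameter averages k Poisson reads per state, modelling
additional acquisitions inserted into the off-switching ramp (default
k = 1).

Accuracy is the mean absolute deviation
MAD = (|Θ₁−Θ̂₁| + |Θ₂−Θ̂₂|)/2, summarized per condition by median,
quartiles and full-range whiskers, against a negative control of
uniformly random guesses (whose MAD converges to (b−a)/3 = 0.2 on
[0, 0.6]). Default photon-budget grid: {250, 1000, 4000, 16000};
contrast sweep at fixed budget 4000 with the photostatic donor's ρ₀ in
{0.5, 0.75, 1.0}. The shipped study and acceptance script use 500
simulations per condition, enough to stabilize the medians to a few
percent; solver failures are counted per condition, never aborting a
study. Seeded runs are bit-reproducible.

What passing these simulations does *not* show about real data: cells
add autofluorescence, imperfect cross-talk correction, photobleaching
during the switching cycle, incomplete off-switching fatigue, and
biosensor two-state behaviour that breaks the ρ₀^(1−Θ) law — which is
why empirical calibration is the supported path for live-cell work.

## Time-lapse analysis

ROI traces are per-frame means over each labeled cell region minus the
mean of a background region outside the cells; negative
background-corrected values are floored at zero and flagged.
Photobleaching baselines:

- FRET traces: fit of exp(−t/τ)·(b + A/(1 + exp((t₀−t)/r))) over the
  full trace (τ decay time in s, typically much longer than the
  experiment; b baseline level; A response amplitude; t₀ half-rise time
  in s; r rise time constant in s). The baseline is b·exp(−t/τ). τ is
  bounded below at a tenth of the trace duration to exclude degenerate
  fast decays. Because A and b are degenerate on responseless traces, a
  reduced pure-decay fit (A = 0) is also computed and preferred when it
  explains the trace equally well.
- Intensity traces with repeated transients (calcium-sensor-like): a
  bi-exponential fitted only to user-designated quiet intervals.

Responses are % Increase(t) = (signal − baseline)/baseline × 100,
invariant to common rescaling of signal and baseline. Per-interval
metrics use half-open intervals [start, end) in seconds from acquisition
start. The maximal response is reported as-is (an all-negative response
keeps its sign). Onset times: a sigmoid fit A/(1+exp((t₀−t)/r)) whose
onset is the time at 7.6% of the fitted maximum, t₀ − r·ln(1/0.076 − 1)
(the 0.076 constant is stored verbatim, three decimals); or the argmax
of the second derivative after a 5-sample local-quadratic
(Savitzky–Golay) smoothing, for transient responses. Traces with no
detectable rise return an absent onset.

Response classification is k-means (default k = 3, 25 restarts, fixed
seed) on per-cell maximal responses over the designated intervals,
z-scored per feature; labels are canonicalized 1..k by descending
cluster size so numbering is stable.

## Problem sizes and determinism

The test suite and acceptance script run the grid inversion on a 50×50
efficiency grid (with a brute-force residual-search oracle on a
subgrid), 500 simulations per noise-study condition, 4-cell 24-timepoint
image fixtures, and 45-cell classification sets; everything is seeded
and completes in seconds. Synthetic calibration sets use 200 points,
matching the scale of pooled multi-cell calibration data.

## Known limitations

- The fixed-point iteration has no global convergence guarantee for
  arbitrary empirical calibrations; the damping handles the oscillatory
  cases seen in practice and non-convergence is always flagged.
- Unmixing is per-ROI/per-pixel independent; no spatial regularization.
- The dark-acceptor variant recovers only the donor-channel split, not
  the dark pair's efficiency.
- Incomplete off-switching that plateaus is handled only through
  empirical calibration kinds, not by an extended analytic law.
- The camera model is pure Poisson; detectors with significant read
  noise or EM gain need their own noise model upstream.
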