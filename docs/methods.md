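# Methods

This note records the models behind `retinaln`, the conventions and
numerical choices baked into the estimators, what the synthetic generators
do and do not emulate, and how the two cell presets were calibrated.

## Stimuli

All stimuli are spatially uniform light-intensity traces; contrast is Weber
contrast relative to the mean level everywhere.  The noise ensemble draws
white Gaussian samples at the analysis rate (default dt = 1 ms), applies an
ideal zero-phase brick-wall low-pass (default 0–60 Hz), rescales to the
requested contrast SD (default 50% of the mean), and clips at zero
intensity without re-normalizing — a physical light source cannot go
negative.  At 50% contrast about 2.3% of samples clip; the realized
contrast SD drops by ~2% and a small amount of distortion power leaks out
of band (tested to stay below 1% of the in-band power).  The clipped
fraction is recorded on the trace.  Steps default to the 0.5-s, 50%
protocol; paired flashes to 400% contrast, 10-ms flashes at onset-to-onset
intervals of 50/100/200/400 ms, with a single-flash companion trace used as
a subtraction template.

One open reading: a "0–60 Hz" noise band could also mean sample-and-hold at
a display refresh; we implement it as a continuous low-pass, which is the
simplest faithful interpretation and is what every test assumes.

## LN estimation

Filters live on a causal lag axis with taps in response-units per unit
contrast per second; the generator signal is the dt-scaled discrete
convolution, making tap values invariant to the sampling rate.  A display
helper provides the conventional reversed-time axis for STAs; all
computation is lag-forward, so a zero-cross reported at +0.080 s
corresponds to −0.080 s on the display axis.

The continuous-response filter estimator divides the stimulus–response
cross-spectrum by the stimulus power spectrum with ridge regularization
ε = 1e−6 · max|S|², and hard-zeros frequencies above the stimulus bandwidth
before inverting: the division is unconstrained where the stimulus carries
no power.  The raw periodogram is used by default (exact per-bin
inversion); an optional frequency-smoothed denominator trades a small bias
for lower variance under heavy response noise.  STA computation offers an
FFT-accelerated path and a direct segment-averaging path computing the
identical quantity (they agree to 1e−10 and cross-check each other in
tests); spikes earlier than one window after stimulus onset are excluded
and counted.

The static nonlinearity uses equal-count (quantile) bins — default 20 bins,
minimum 50 samples per bin, under-filled bins merged with a neighbor — with
bin centers at the within-bin mean of the generator signal.  Prediction
interpolates linearly between bin centers and extrapolates as a constant
beyond the end bins.  Model performance is the Pearson correlation between
prediction and trial-mean response, burn-in removed.  Equal-count binning
was chosen over equal-width because it is robust to the generator-signal
density; bin count and regularization are exposed because no single
convention is canonical for this procedure.

## Kinetics statistics

The initial lobe of a filter is the earliest local extremum whose magnitude
exceeds `noise_floor_frac` (default 0.1) of the waveform's absolute
maximum; the zero-cross is the first sign change after it, interpolated
between samples; the biphasic index is the magnitude of the largest
opposite-sign excursion after the crossing divided by the initial-lobe
magnitude (for triphasic waveforms this picks the dominant secondary lobe).
Both metrics are invariant to gain and sign flips.  For *estimated* filters
the pipeline raises the floor to 0.3: in-band estimation ripple in the flat
early-lag region can otherwise masquerade as an initial lobe — this is
precisely what the guard parameter exists for, and the clean-kernel default
stays at 0.1.

Step kinetics subtract the mean over a pre-onset baseline window, take the
largest-magnitude excursion within the step as the peak (its sign defines
the positive direction, so inward-current responses need no special
casing), and report the mean over the final steady window as a percentage
of the peak — default last 100 ms of a 0.5-s step (the electrophysiology
convention), with the 2-s/last-1-s fluorescence convention available by
argument.  Time to peak is measured to the end of the peak sample, so an
ideal square pulse reports one sample interval.  Values above 100% are
flagged rather than clamped.

The paired-flash ratio measures the first-flash peak from the single-flash
template and isolates the second-flash response by subtracting the template
from the paired trace — exact under linear superposition, and the least-
assumption way to separate responses that overlap at the 50-ms interval.  A
flag switches to the raw post-onset peak for comparison.

## Depressing-synapse model

A single readily-releasable pool with occupancy p ∈ [0, P0]:

    dp/dt = (P0 − p)/τr − k·max(d − θ, 0)·p,    R = k·max(d − θ, 0)·p

integrated by explicit Euler at dt = 1e−4 s.  A stability guard raises an
error (with a suggested dt) whenever the per-step loss fraction would reach
one, rather than silently clamping; under the guard occupancy respects its
bounds exactly and halving dt changes release traces by well under 1% RMS.
Useful closed forms, both verified in tests: sustained release for constant
suprathreshold drive, R_ss = k·d·P0/(1 + k·d·τr); and the impulse
approximation for two brief pulses, ratio ≈ 1 − f·exp(−Δt/τr) with f the
per-pulse depletion fraction.

One pool is deliberately minimal: pool size, release-rate constant,
threshold and refill time are the four knobs the data patterns require
(transience, paired-flash depression, recovery with interval).  A
reserve-pool cascade, calcium-channel biophysics and multivesicular release
are out of scope.  Note that the paired-flash ratio and the steady-state
fraction are both independent of P0 in this model — pool size is a pure
gain — so the kinetic contrast between presets is carried by (k, θ, τr),
with P0 kept as the amplitude knob consistent with the anatomy it stands
in for.

## Forward sensors

EPSCs convolve the release rate with a unit-area exponential quantal kernel
(τ = 2 ms) scaled by a quantal amplitude (1.5 pA), inward-negative; the
absolute scale is an order-of-magnitude placeholder and no test depends on
it.  Fluorescence convolves release with an exponential sensor kernel
(area = sensor τ), averages within imaging frames at 58.25 Hz and adds
frame noise.  Sensor kinetics are likewise placeholders: tests use only
relative and steady-state properties.

## Conductance decomposition

Currents recorded at the inhibitory reversal (−68.5 mV, the chloride
reversal of the emulated recordings) and at the excitatory reversal (0 mV,
the standard cation-reversal assumption, exposed as a flag) are divided by
the respective driving forces: g_exc = I(E_inh)/(E_inh − E_exc),
g_inh = I(E_exc)/(E_exc − E_inh), pA/mV → nS.  No series-resistance or
space-clamp correction is applied.  Negative conductance excursions beyond
a tolerance are counted as a wrong-reversal diagnostic.  The peak ratio
takes the maxima of the two traces independently (they need not be
simultaneous), on trial-averaged conductances.

## Ribbon morphometrics

The generator draws per-type lognormal ribbon volumes (CV 0.4) with type-6
ribbons 2.5× the type-5i mean — the middle of the ~2–3× range — and vesicle
counts round(slope·V + noise) floored at zero.  The default count-noise is
set by a variance-matching rule, σ² = Var(slope·V)·(1 − r²)/r² with
r² = 0.66, so the pooled regression lands at the target coefficient of
determination.  The default regression direction is volume on count (a
slope of order 1e−6 µm³/vesicle is only dimensionally sensible that way);
because the noise lives on the counts, that direction attenuates the slope
by exactly r², and the generator's default slope is therefore
0.66/6.98e−06 ≈ 9.46e4 vesicles/µm³ — the unique value for which the
default-direction fit reproduces both the target β (≈ 7e−06) and r²
(≈ 0.66) simultaneously.  Both fit directions are supported and tested;
OLS inference (slope p-value, r²) comes from statsmodels.  Group summaries
use linear-interpolation quartiles with 1.5·IQR whiskers clipped to the
data range.

## Cell presets and calibration

`presets.yaml` freezes two cells.  Filter kernels are differences of
unit-peak gamma functions (order 6, τ_damp/τ_rise = 1.6) solved exactly, on
a 10-µs grid of the continuous kernel, for the target kinetics: the
transient preset at zero-cross 0.080 s / biphasic 0.63, the sustained
preset at 0.072 s / 0.43, with matching inhibitory kernels at indices
0.34 / 0.16.  Response noise is frozen at the level that puts held-out LN
performance near r ≈ 0.55 (transient) and 0.65 (sustained) for 5-trial
means.  The shared presynaptic (bipolar) kernel is mildly biphasic and
scaled so a 50%-contrast step drives a unit plateau at the synapse.

Synapse parameters were calibrated by simulating the exact measurement
protocols.  The paired-flash anchors (ratio 0.04 transient / 0.29 sustained
at 50 ms) are met exactly.  They constrain the model strongly: a 50-ms
ratio of 0.04 forces near-total per-flash pool depletion with τr ≳ 1.5 s,
and carrying that much depression through a sustained 0.5-s step caps the
EPSC steady state near 4% of peak (transient) and 26% (sustained).  Larger
steady-state percentages, as reported for glutamate-sensor measurements
under different solutions and windows, are not simultaneously reachable in
a single-pool model — we mapped the (k, θ) feasibility frontier numerically
and took the maximum attainable steady state subject to the paired-flash
constraint.  All cross-preset orderings (biphasic index, steady-state %,
paired-flash ratio) hold with margin on every tested seed; the absolute
steady-state numbers are a documented limitation of the minimal model, not
of the estimators.

## What the generators do and do not emulate

The synthetic world is exactly LN-plus-depression: Gaussian (clipped) noise
statistics, stationary filters, memoryless output nonlinearities, additive
white response noise, Poisson spiking with absolute refractoriness, and one
vesicle pool per cell.  It omits spatial structure (all stimuli are
full-field), photoreceptor and network adaptation, amacrine circuitry,
correlated/trial-structured noise, spike bursting, and dyad-level release
heterogeneity.  Passing tests therefore certify the estimators and the
model's internal consistency on data that satisfies the model's
assumptions; they do not certify behaviour on real recordings that violate
them.

## Problem sizes and determinism

Defaults used by the pipeline and the results script: 300-s noise fits at
1 kHz, 10-s repeated segments × 5 trials, synapse integration at 10 kHz,
three simulated cells per preset, 150-ribbon tables; the full test suite
runs in well under a minute on one CPU.  Every random stage takes an
explicit seed (derived stably from one base seed per cell via CRC32), no
output embeds timestamps, and identical configurations reproduce the
metrics table byte for byte.
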