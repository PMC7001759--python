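# Methods

This note documents the models, estimators, defaults and numerical choices
behind `spikespatial`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Conventions

Time is in seconds with t = 0 at session start; all binning is half-open
`[a, b)`. Positions are in cm, head direction in degrees counter-clockwise
from the +x axis in `[0, 360)`, angular velocity signed with positive =
counter-clockwise. LFP phase is 0° at the peak of the (band-passed)
oscillation and increases through the cycle, so a trough-firing unit has
mean phase 180°. Spikes whose analysis window would cross a recording
boundary are dropped, never padded.

## Kinematics

Speed and angular velocity are central differences of the position and the
unwrapped heading after a 0.4 s boxcar (default), which suppresses tracker
jitter that otherwise dominates derivatives at 50 Hz. Unwrapping before
differencing prevents spurious ±18 000 °/s spikes at the 0/360 crossing.
Border distance is measured to the arena boundary estimated as the convex
hull of the whole path; the hull is robust to corner-cutting trajectories,
unlike wall detection from coordinate extrema, but will overestimate
distance in genuinely concave arenas (a known limitation). For degenerate
paths (1-D motion) the boundary is undefined and the border channel is left
unset.

## Rate maps and their statistics

Maps use 3 cm bins. Spike counts and dwell are smoothed separately with a
5×5 boxcar *before* division (the alternative — smoothing the raw-rate map
after division — is available via `smooth_order="post"`; which order an
analysis pipeline uses is a genuine free choice and changes bin-level
values slightly, so it is exposed rather than hidden). Bins with under
0.1 s of raw dwell are masked: their rate estimates would be dominated by
single-sample noise. Spatial coherence is always computed on the
*unsmoothed* map, since it is itself a smoothness measure. Skaggs
information and sparsity use the smoothed rate with occupancy weights;
both are exact identities on uniform maps (0 bits; sparsity 1), which the
tests pin to 1e-12 against direct summation.

Place fields are the 4-connected component above 0.2 × peak containing the
global peak, requiring ≥ 9 bins; the centroid is occupancy-weighted over
member bins. The spatial autocorrelogram is the Pearson correlation at
every integer bin offset over pairwise-complete visited bins, masked below
20 overlapping bins. Gridness uses an annulus from the central-peak radius
(connected region > 0.3) to 1.2 × the median radius of the six nearest
peripheral peaks; with fewer than six peaks a fallback outer radius (80% of
the map half-width) is used and the score flagged low-confidence. Rotations
are bilinear; annulus bins whose rotated counterpart leaves the valid
region are excluded.

## 1D tuning

Defaults: HD 5° bins; speed 2.5 cm/s bins capped at 40 cm/s; angular
velocity 10 °/s bins capped at ±200 °/s; border distance 3 cm bins. Spike
variable values are interpolated at spike times (circularly for angles).
Linear fits are occupancy-weighted least squares with the *dwell-weighted
mean* of the variable per bin as the abscissa: regressing on raw bin
centres attenuates slopes measurably (≈ 7% for speed under the simulator's
speed distribution) because dwell within sparsely occupied tail bins is
skewed. The Rayleigh p-value uses the standard large-n approximation
(accurate beyond n ≈ 10); κ comes from the resultant length via the usual
piecewise approximation. The tuning half-width is measured at half the
peak rate above a *zero* baseline (the alternative — above the background
rate — is not used; for broadly tuned cells with high baselines the two
differ, which is why the convention is stated here). The preferred
direction reported as `preferred_direction` is the bin-resolved curve peak;
parameter-recovery comparisons use the circular `mean_direction`, which is
far less noisy for broad tuning.

The distributive prediction computes, for each variable bin, the
dwell-weighted mean of the locational rates experienced while the variable
was in that bin, and summarises the observed/predicted discrepancy as
`mean |ln((1+obs)/(1+pred))|`. Under the simulator's isotropic random walk
the sampling bias of a place cell is weak, so the test pins the contrast
(place-cell ratio ≲ 0.15, HD-cell ratio several-fold larger) rather than a
high absolute prediction-observation correlation; strongly constrained
real trajectories produce much stronger apparent tuning and correlations.

## Randomization

Surrogates are circular shifts of all spike times by
Uniform[20 s, duration − 20 s) — this preserves the spike count and the
ISI multiset up to one wrapped interval, so rhythmicity cannot leak into
the null. An i.i.d. redraw mode exists for comparison. Defaults: 500
surrogates, 95th percentile. The time-shift profile uses a −0.2 s to
+0.4 s grid in 25 ms steps (configurable); the asymmetric default is kept
deliberately, as forward shifts are the physiologically interesting
direction for latency. Time-lapse windows share the whole-session bin
geometry so maps are comparable; the final cumulative window equals the
whole-session analysis exactly.

## Multivariate regression

Observed rate is the spike count per 100 ms bin divided by the bin width.
Each of the five predictors (location, HD, speed, AHV, border distance)
enters as the unit's average-rate value at the state in that bin — the
appropriate encoding for idiosyncratically shaped tuning, which makes each
column the best linear carrier of "what this variable alone would
predict". States outside a curve's range are clamped to edge bins; bins in
unvisited locations are dropped (error if over half drop). Predictive
power is the semi-partial r² (R² drop on removing one predictor); partial
r² is reported alongside, and is the quantity used for population
clustering. Exactly collinear or constant columns are dropped with a
warning. Classification standardizes coefficients, runs k-means (k = 2
default, 20 restarts, fixed seed) and names the cluster whose centroid has
the largest HD coefficient the HD cluster.

## Spike–LFP coupling

Band defaults: delta 1–4, theta 4–12, beta 12–30, gamma 30–80 Hz;
frequency grid 1–40 Hz in 1 Hz steps; analysis window ±0.5 s around each
spike. SFC divides the STA's Hann-tapered power spectrum by the mean
spike-segment power spectrum with the identical taper, which bounds it in
[0, 100] by construction. PLV uses the phase of each spike-segment's
windowed Fourier coefficient (the filter–Hilbert phase route is used for
the phase *distribution*; absolute PLV values from different estimators
are not comparable across packages). The phase distribution band-passes
with a 4th-order zero-phase Butterworth before the Hilbert transform.
Time-resolved metrics recompute all three on windows centred at spike time
plus each lag in a ±0.2 s grid (25 ms steps) and report the lag maximising
the band-mean of each metric. On a strictly stationary oscillation every
lag locks equally, so lag recovery is only meaningful — and only tested —
with transient oscillatory events.

## Theta indices

The autocorrelogram (5 ms bins, ±0.5 s window) is fitted over positive
lags with `a·cos(2πfτ)·e^(−|τ|/d) + c`, f restricted to 4–14 Hz, by
least squares with 8 restarts (one at 8 Hz, the rest drawn from a fixed-
seed RNG). Modulation index = `a/(a+c)` clipped to [0, 1]. The skipping
index refits with an added half-frequency component at fixed f and reports
`|s|/(|a|+|s|)`; only the half-frequency term can absorb alternate-cycle
peak inflation. Both indices are amplitude ratios and therefore invariant
to count rescaling. Absolute skipping values are estimator-specific and
should only be compared within this package.

## Cluster separation

Bhattacharyya distance uses the Gaussian closed form on sample moments —
stable in ≥ 4 feature dimensions at realistic spike counts, where
histogram density estimates are not; the Gaussian assumption is the
documented trade-off. Singular covariances are ridge-regularized
(1e-6 × trace/dim) with a warning. Hellinger = √(1 − BC) by construction.

## Synthetic sessions

The simulator emulates: a correlated random walk (heading random walk,
turn SD 12°/step at 50 Hz; folded-normal steps, 0.35 cm scale → mean speed
≈ 13 cm/s) reflected at the walls of a 100 cm square (or circular) arena;
head direction = movement heading + von Mises jitter (κ = 20), so heading
and locomotion are correlated but not identical; inhomogeneous-Poisson
spikes by Lewis–Shedler thinning against closed-form tuning functions
(Gaussian place field; von Mises HD tuning; three-plane-cosine grid with
wave number 4π/(√3·spacing), rescaled and clipped at zero; exponential
border-distance decay; clipped-linear speed tuning); theta units locked to
a noisy sinusoidal LFP through a von Mises phase modulation of the rate;
Gaussian-windowed theta wavelets at spike + lag for lag-recovery ground
truth; and Gaussian waveform-feature clusters. Standard study conditions
throughout tests and the acceptance script: 600 s sessions, 50 Hz
tracking, peak rates ~12–15 Hz, baselines 0–0.5 Hz.

What it does *not* emulate: overdispersed (non-Poisson) firing, theta
phase precession, slow drift of fields or electrodes, tracking dropouts,
non-convex arenas, multi-unit contamination, and realistic 1/f LFP
backgrounds. Passing parameter-recovery tests therefore demonstrates
estimator correctness and calibration under the stated model, not
robustness to every artefact of real recordings.

## Problem sizes

The test-suite and acceptance-script simulations use 600 s sessions (the
shuffle size check runs 100 of them with 500 surrogates each; power and
regression checks use 20 runs each; coupling checks use 120–250 s LFP
segments at 250 Hz). These sizes make all statistical bounds comfortably
stable at fixed seeds while keeping a full run in the minutes range on a
single CPU.

## Reproducibility

All generators and analyses that use randomness take explicit seeds; the
per-unit driver derives one seed per unit from the configuration seed, so
a fixed configuration reproduces the exported results CSV byte for byte.
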