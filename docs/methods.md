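# Methods

This note documents the analysis model implemented by `speedcells`, its
parameter defaults, the synthetic-data model used to validate it, and
the numerical and design choices made where the procedure was genuinely
open.

## Kinematics

Two-LED tracking at 30 Hz is linearly interpolated onto a uniform
25.6-ms grid; missing video frames are bridged, but bins inside tracking
gaps longer than 1 s (configurable) are masked invalid. Position is then
smoothed by local linear regression with tricube weights over an 11-bin
(281.6 ms) window — the classic span-based lowess smoother; at the
series edges the window slides inward rather than shrinking. Speed is
the Euclidean displacement between adjacent smoothed positions divided
by the bin size, then Gaussian-smoothed with SD 512 ms. Head direction
is the atan2 of the front-minus-rear LED vector per bin.

The Gaussian kernel is truncated at ±4 SD and renormalised wherever part
of its mass falls outside the defined data (series edges, masked bins),
so a constant input stays constant everywhere. The smoothing SD is
configurable among {128, 256, 512, 1024} ms for sensitivity analyses;
512 ms is the default used everywhere else.

Analysis is restricted to locomotion: bins with speed in [2, 50] cm/s
(inclusive on both ends, configurable) and valid tracking. The full
speed series is smoothed first and masked afterwards; masking before
smoothing would propagate gaps into neighbouring bins and make the mask
kernel-dependent.

## Speed coding

The instantaneous firing rate is the 25.6-ms spike count divided by the
bin size, smoothed with the same kernel policy as speed. The **speed
score** is the Pearson correlation between rate and speed over valid
bins (undefined — not zero — when fewer than 100 bins are valid or
either series is constant). The **speed slope** and **normalised speed
slope** are OLS slopes of rate (or rate/mean-rate) against speed.

**Speed information** bins speed into twelve 4-cm/s bins on [2, 50];
with occupancy probabilities pᵢ, per-bin mean rates λᵢ and overall mean
λ = Σ pᵢλᵢ, information per spike is Σ pᵢ(λᵢ/λ)log₂(λᵢ/λ) and per
second Σ pᵢλᵢlog₂(λᵢ/λ), with 0·log 0 := 0. The identity
per-second = λ × per-spike holds algebraically for any λ and is asserted
to 1e-10 on every unit. Unoccupied bins are excluded from the pᵢ
normalisation. The same operation computes spatial and head-directional
information.

**Temporal shift.** r(τ) correlates the rate at time t with the speed at
t + τ for τ ∈ [−1536, +1536] ms in 25.6-ms steps (121 lags); the lag
maximising r is the preferred temporal shift. Sign convention: positive
= the rate leads (predicts) speed = prospective coding; negative =
retrospective. Diagrammatically, for a unit with λ(t) = f(v(t + Δ)),
Δ > 0, the rate at t carries information about speed Δ later, so r(τ)
peaks at τ = +Δ. Units whose argmax falls on either boundary are flagged
excluded. The speed mask is evaluated at the speed timestamp; bins
shifted off the session edge are dropped (no wraparound — wraparound is
reserved for the shuffle). The zero-lag entry shares the code path with
the speed score, so r(0) equals the score bit for bit.

**Shuffle null and classification.** Each surrogate adds a single random
offset, uniform on [30 s, T − 30 s], to all spike times modulo the
session length, then re-runs the full binning-and-smoothing rate
pipeline against the untouched speed series (speed is unaffected by
spike shifts, so nothing about the mask is recomputed). 100 surrogates
per cell. Classification pools surrogate scores across all cells and
takes the pooled 1st/99th percentiles as thresholds, applied by strict
inequality; per-cell thresholds are available by configuration.

## Theta analysis

Theta epochs are detected automatically from the ratio of 5–11 Hz power
to the summed 1–4 and 12–14 Hz power in 2-s windows stepped by 1 s
(Welch estimate with four averaged segments per window — a single
periodogram's band-ratio variance triggers false detections in broadband
noise); windows with ratio > 2 are merged and epochs shorter than 1 s
dropped. All thresholds are configurable; they replace a manual
adjustment step, so epoch boundaries on real data may differ by a window
step.

Spike phases: the LFP is band-pass filtered at 5–11 Hz with a
zero-phase (forward-backward) 3rd-order Butterworth filter, the
instantaneous phase comes from the Hilbert transform, is unwrapped,
linearly interpolated at spike times and wrapped modulo 2π. Convention:
positive LFP peaks = 0/2π, troughs = π (positive polarity up). Phase
assignment is invariant to LFP amplitude scaling. Only spikes inside
theta epochs during locomotion enter phase statistics. The preferred
phase and resultant length R are the circular mean and first-moment
magnitude.

The theta index uses the 5-ms-bin autocorrelogram of the same spike
subset: (mean count 100–140 ms − mean count 50–70 ms)/(their sum),
0 when the sum is 0, undefined below 100 spikes. Cells above 0.2 are
theta-modulated. Autocorrelogram counts are raw coincidence counts; the
index is scale-free, so rate normalisation is irrelevant.

## Spatial coding

Rate maps bin position into 3 × 3 cm pixels during > 2 cm/s locomotion;
occupancy and spike-count maps are smoothed separately with a Gaussian
kernel (SD 3 cm) and divided, and rate is defined only where the
smoothed occupancy of visited bins is positive. Head-direction tuning
uses sixty 6° bins with time-based occupancy and no smoothing.

The spatial autocorrelogram evaluates, for every lag, the Pearson
product-moment formula over the n bins where the rate is defined in both
the original and the shifted copy (edge correction); lags with n < 20
are undefined. The gridness score finds the central-peak radius (first
local minimum of the radial correlation profile, or first crossing below
0.2, whichever comes first), then forms expanding annuli whose outer
radius grows in one-bin steps from central + 10 cm to the arena side
− 10 cm. Each annulus is correlated with its rotation (bilinear
interpolation about the centre; samples touching undefined bins are
excluded pairwise) at 60° and 120° versus 30°, 90° and 150°; the annulus
score is min(r₆₀, r₁₂₀) − max(r₃₀, r₉₀, r₁₅₀) and the gridness is the
maximum annulus score. The annulus step equals one rate-map bin (3 cm),
configurable.

## Cell classification

**Excitatory/inhibitory.** For each ordered pair, the cross-correlogram
(1-ms bins, ±20 ms) is compared against global 99% acceptance bands
built from 1000 surrogates in which every spike of both trains is
independently jittered on ±5 ms; each band is the 99th (1st) percentile
across surrogates of the per-surrogate maximum (minimum) over the whole
interval. A connection is excitatory when the observed count exceeds the
upper band in any bin at 1–5 ms latency, inhibitory when any such bin
falls below the lower band; same-electrode pairs ignore the 0–1 ms bin.
No multiple-testing correction is applied across pairs. Jitter-labelled
units seed a linear discriminant in the (trough-to-peak latency,
waveform asymmetry) plane, which labels the remaining units; with fewer
than five labelled units per class a configured fixed boundary is used,
and units within a configurable margin of the hyperplane are flagged
low-confidence.

**PV vs SOM.** From the 1-ms autocorrelogram: burst amplitude = mean
count over 0–10 ms minus the 40–50 ms baseline; burst index = amplitude
divided by the larger of the two, hence in [−1, 1]. (The mean, rather
than the maximum bin, over 0–10 ms is used: for a flat autocorrelogram
the max-bin estimator is biased upward by roughly +0.15, while the mean
is unbiased; the ordering of bursty vs non-bursty cells is unchanged.)
The refractory period is the first bin at which the first difference of
the autocorrelogram, taken from 0 ms to the global autocorrelogram peak
within 0–50 ms, exceeds one SD of those differences; differences are
unsmoothed by default. PV: burst index > 0 and refractory < 7 ms; SOM:
burst index < 0 and refractory > 4 ms; anything else unclassified.

**EC2 stellate vs pyramidal.** Decision regions in (preferred phase, R)
space relative to the local EC2 theta are configuration data, not code.
The shipped default regions are synthetic placeholders encoding only the
qualitative picture (pyramidal cells strongly locked near the local
theta trough, stellate cells weaker and nearer the peak); any real claim
requires supplying the calbindin-calibrated boundaries through the
config. Units on a region boundary remain unclassified.

## Synthetic sessions

The generator emulates the statistical structure of an open-field
recording, not its biophysics:

- **Trajectory** — speed follows an Ornstein–Uhlenbeck process (mean
  16 cm/s, reversion 0.5 s⁻¹, noise 8 cm/s·s^−1/2) reflected at zero,
  chosen so the large majority of time falls in the analysable
  2–50 cm/s band, as in foraging rats; heading is a Gaussian random
  walk (1.2 rad·s^−1/2) reflected at the walls; the rear LED sits 12 cm
  behind the front LED along the heading. 30 Hz frames.
- **LFP** — an 8 Hz cosine (positive peaks = phase 0) with optional
  speed-modulated instantaneous frequency plus white noise, at 1250 Hz.
- **Units** — inhomogeneous Poisson by exact thinning on a 1-ms
  piecewise-constant rate: λ(t) = max(0, baseline + gain·v(t + lag)) ×
  von-Mises theta gain (normalised to unit mean) × optional
  place/grid/head-direction gain (normalised to unit mean over the
  trajectory). Optional burst doublets are appended per spike with a
  stated probability and intra-burst interval, and an absolute
  refractory period is enforced last. A positive lag makes the rate
  encode future speed (prospective). Each unit draws from its own RNG
  stream keyed by (master seed, unit index), so adding units never
  perturbs existing ones.

What the generator does **not** emulate: place-field theta phase
precession, rate remapping, slow drifts in excitability, correlated
noise across units, realistic pause/run behavioural segmentation, spike
sorting errors, or volume-conducted LFP structure. Passing recovery
tests therefore shows that the estimators are correct and calibrated
under the stated statistical model, not that they are robust to every
artefact of real recordings.

## Validation scales and numerical choices

The validation suite works at desk scale: 20-minute sessions, 30 units
for parameter recovery, 500 unmodulated units for null calibration (100
shuffles each), 100 seeded runs for monosynaptic detection sensitivity
and 500 independent pairs for its false-positive rate. These sizes give
binomial/Monte-Carlo error small enough for the stated tolerances while
keeping the whole suite within minutes on one core.

Recovery of the speed gain is measured at the unit's recovered preferred
shift (the zero-lag slope of a lagged unit is attenuated by the speed
autocorrelation). Recovery of the temporal lag is summarised as the
median preferred shift per true-lag group over units with gain
≥ 0.25 Hz/(cm/s): single-unit argmax estimates of a smooth correlation
curve jitter by one to three 25.6-ms bins at these session lengths, so
the population median is the meaningful recovery target — matching how
population temporal biases are reported.

Other numerical choices: correlogram bin edges are built as integer
multiples of the bin width (a subtractive construction misplaces exact
lags by half an ULP); undefined statistics are returned as NaN with an
explicit flag rather than silently coerced to zero; percentiles use
linear interpolation; ties in the shift-curve argmax resolve to the
most negative lag (first occurrence). Degenerate inputs (constant
series, empty phase sets, all-zero LFP, too-few-spike units) are flagged
undefined and logged, never dropped from unit tables.

## Known limitations

- Theta-epoch detection replaces the manual curation used on real data;
  on real recordings epoch boundaries (and everything conditioned on
  them) can differ by a detection step.
- The EC2 stellate/pyramidal default boundaries are placeholders (see
  above).
- The session reader covers the classic Neuroscope layout only; dialect
  deviations must be absorbed by the layout config.
- Headline population fractions from the source recordings (proportions
  of p-/n-Speed cells per region and cell type) require the original
  deposited data and are out of desk-scale reach; the pipeline exposes
  the cohort summary tables needed to reproduce them once those
  recordings are available.
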