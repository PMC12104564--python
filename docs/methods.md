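# Methods

`nociscreen` implements the analysis stack of an MEA-based phenotypic
screen for analgesic candidates on iPSC-derived sensory neuron-like
cells carrying a gain-of-function Naᵥ1.7 (SCN9A) mutation. This note
records the models, conventions and numerical choices, and what the
synthetic-data tests do and do not establish about real recordings.

## Spike detection (`spikes`)

Raw per-electrode voltage (µV, 20 kHz) is band-pass filtered between
1 and 10 kHz with a 2nd-order zero-phase Butterworth (applied
forward–backward, so spike timing is not skewed). The literal 10 kHz
upper edge equals the Nyquist frequency at 20 kHz sampling and is
clipped to 0.45 × the sampling rate with a warning; both edges are
configurable.

The detection threshold is ±5 × the baseline noise SD. The SD is
estimated on the whole filtered trace as 1.4826 × the median absolute
deviation — the standard spike-resistant estimator; with 1 Hz of large
spikes on a 300 s trace the estimate moves by well under 5% where a
plain SD moves far more. A spike is registered at the first sample
whose absolute value crosses threshold (either polarity); after each
trigger the detector stays disarmed for the 1 ms pre-trigger +
2 ms post-trigger dead time, so no two detections are closer than
3 ms. The acquisition-software wording leaves open whether "pre-trigger"
refers to lockout or to waveform cut-outs; we implement it as lockout,
which is the conservative reading for rate estimation.

Mean rate is count/duration over the 300 s window; a channel is
*active* iff its rate strictly exceeds 0.33 Hz.

## Screen statistics and hit calling (`screen`)

Channels active at baseline form the paired lists; `n_active` counts
them (the phase that defines activity is not fixed by the protocol
text; baseline is the natural choice because the pairing exists to
measure suppression of pre-existing firing). Per compound:

- **normalised activity** = 100 × mean(after)/mean(before) — the ratio
  of means, not the mean of per-channel ratios, which would be
  dominated by low-rate channels;
- **Wilcoxon signed-rank p**, two-sided, zeros excluded; p = 1 when
  all differences vanish;
- **Benjamini–Hochberg FDR** across the compound library (one p per
  compound — the funnel reports per-compound significance);
- **robust z′** = (median(after) − median(before)) / pooled raw MAD,
  pooled as the root mean square of the two unscaled MADs. No 1.4826
  factor: the statistic is expressed in MAD units as a nonparametric
  analogue of the z-score;
- **Cohen's d** with the classical pooled-SD (n₁+n₂−2) denominator.

A hit requires *all* of: normalised activity < 50%, FDR-adjusted
p < .01, |z′| > 1.96, |d| > 0.80, n_active ≥ 9. An optional sixth
criterion (median separation ≥ 2 pooled MADs, i.e. |z′| ≥ 2) can be
switched on; it is off by default because the main protocol text omits
it. Hits are tiered by reduction r = 100 − normalised activity:
high (r > 90), moderate (70 < r ≤ 90), low (50 < r ≤ 70) — the three
intervals partition (50, 100].

## Concentration–response models (`doseresponse`)

MEA activity follows a two-parameter inhibitory Hill curve with fixed
asymptotes, A(c) = 100/(1 + (c/IC50)^n): screen activity is already
baseline-normalised, so the asymptotes carry no free information, and
inhibition is exactly 50% at c = IC50 by construction.

Patch-clamp inhibition fractions follow a Boltzmann sigmoid in
*linear* concentration, B(c) = emax/(1 + exp((IC50 − c)/h)). The slope
factor h carries µM units; the linear form is used because reported
slope factors (up to ~70) are far beyond any plausible log-domain Hill
coefficient and have concentration-like magnitude. Consequences worth
knowing: B(0) = 1/(1+exp(IC50/h)) is not exactly zero when IC50 is not
much larger than h, and compounds that do not fully block the
TTX-sensitive current are handled by freeing emax (fixed at 1 by
default).

Fitting minimises the SSE with bounded trust-region least squares
(`scipy.optimize.least_squares`, xtol/ftol/gtol 1e-12), multi-started
from ≥ 5 log-spaced IC50 values spanning the observed concentrations;
ties resolve to the lowest SSE, then the smaller IC50. R² =
1 − SSE/SST. When the SSE improves on the constant-mean model by less
than 1% the fit is flagged "no concentration–effect relationship" and
reported unconverged — the behaviour expected for compounds with flat
response curves. Noiseless generate-then-fit round trips recover
parameters to ~1e-9 relative across IC50 ∈ [0.5, 200] µM.

The tiered follow-up grids are fixed: high 10/8/6/4/2/0, moderate
12.5/10/7.5/5/2.5/0, low 16.6/13.3/10/6.6/3.3/0 µM (0 = vehicle).

## Toxicity and reversibility (`toxicity`)

LDH activity is (A490 − A680), normalised between vehicle (0%) and the
lysis positive control (100%), per timepoint (1, 6, 24 h). A compound
is cytotoxic if any timepoint exceeds 5% of the positive control —
worst-case aggregation, the conservative choice where the assay
protocol does not state one.

Recovery after washout is the regained fraction of the inhibited gap,
100 × (washout − post)/(baseline − post), clipped to [0, 100] — i.e.
"how much of the suppressed activity returned", invariant to common
rescaling of the three activities. (An alternative reading,
washout/baseline, is a one-line change; the gap-fraction form is used
because it is well defined for partial inhibition.) Reversibility
requires washout activity to exceed post activity by more than 2 ×
the pooled standard error of the two activity estimates, so Poisson
rate noise does not relabel truly irreversible compounds. Patch-clamp
candidates are non-toxic, reversible compounds with recovery ≥ 60% and
a converged fit with IC50 ≤ 8 µM; the funnel is monotone by
construction (candidates ⊆ reversible ⊆ non-toxic ⊆ hits).

## Patch-clamp feature extraction (`patchclamp`)

Spike-like events in current-clamp sweeps are found with a dV/dt
criterion (≥ 10 mV/ms on a Savitzky–Golay-smoothed derivative, 1 ms
window) so sub-threshold "attempting" events are caught, plus an
amplitude confirmation: the peak must rise ≥ 10 mV above the local
pre-onset baseline. The confirmation is needed because the smoothed
derivative of ~1 mV recording noise occasionally crosses the slope
threshold on long sweeps; genuine events (≥ 20 mV) are unaffected.

Gap-free classes: *quiet* (no events), *attempting sAP* (events that
never reach 0 mV), *spontaneous* (any peak ≥ 0 mV). Current-step
classes use the best step of the −10..180 pA family, with a *train*
defined as ≥ 3 complete (≥ 0 mV) spikes in one step — the protocol
language never quantifies "train"; 3 is the committed choice.

Resting Vm is the mean over the first 30 s with ±50 ms around detected
events excluded. Spike parameters: the threshold is the voltage at the
third-derivative peak on the depolarising limb (derivatives from a
5th-order Savitzky–Golay smooth — raw finite differences make the
third derivative unusable); spike height = peak − threshold; the
half-height width is measured at threshold + height/2 with linear
interpolation at the crossings; AHP is the post-peak minimum
referenced to threshold (not to resting Vm — a committed choice);
rates are the extrema of the first derivative in mV/ms. For a Gaussian
spike the third-derivative maximum sits √(3+√6) σ ≈ 2.33 σ before the
peak, putting the threshold at 6.6% of the amplitude; the resulting
half-height width is 2.245 σ, about 5% below the base-referenced FWHM
2.355 σ — both values are asserted in tests.

Voltage-step families (−70 mV holding; −120..+80 mV in 5 mV steps) are
baseline-subtracted at the holding level. Naᵥ activation = most
negative current in the first 25 ms of the test step; Naᵥ inactivation
= trough in the window between the test step and the final held level
(the published protocol under-specifies the pre-pulse layout; this
window-based reading is the committed interpretation); Kᵥ = mean of
the last 50 ms of the step. Compound inhibition is normalised to the
TTX-sensitive current at the −35 mV step:
ΔI/ΔI_TTX = (I_ctl − I_cmp)/(I_ctl − I_TTX), flagged when outside
[0, 1.05].

## Synthetic data (`synthgen`)

The generator reproduces the *statistical* structure the analysis
assumes, not membrane biophysics:

- **Firing**: homogeneous Poisson per channel with an absolute 3 ms
  refractory period equal to the detector dead time (exponential ISIs
  shortened so the mean rate is exact), so every true spike is in
  principle recoverable. Baseline rates are log-normal across channels
  (median 1.5 Hz, σ_log 0.6) with 75% of channels active — plausible
  values for spontaneously hyperactive cultures; the source study does
  not report the distribution, so these are free parameters, chosen
  once.
- **Pharmacology**: post-exposure rate = baseline × Hill activity at
  the well's concentration; washout rate restores a per-compound
  recovery fraction of the suppressed rate (linear interpolation — the
  study defines reversibility only qualitatively).
- **Waveforms**: a fixed negative-leading biphasic template, 1 ms
  total with a sharp 0.3 ms negative lobe, added to zero-mean Gaussian
  noise (float32). The sharp lobe keeps the template's energy inside
  the 1–10 kHz detection band; a symmetric 1 ms shape concentrates
  energy at ~1 kHz and is attenuated below a 5 SD threshold by the
  band-pass itself.
- **Seeding**: every channel draws from
  `SeedSequence(seed, spawn_key=(well, electrode, stream))`, so output
  is bit-identical for identical inputs and adding wells does not
  perturb existing channels.
- **LDH**: toxic compounds release 20% of the vehicle-to-positive span
  (safely above the 5% cut), non-toxic 1%, with 0.005 absorbance read
  noise.
- **Voltage steps**: stylised Naᵥ transient (biexponential,
  τ 0.5/3 ms) with a Gaussian amplitude envelope peaking at the −35 mV
  step, scaled by (1 − Boltzmann inhibition); a compound- and
  TTX-insensitive delayed-rectifier-like Kᵥ component (midpoint
  −10 mV, so it is essentially closed at −35 mV and does not
  contaminate the Naᵥ measurement); TTX removes the inward component.
- **Current clamp**: Gaussian spikes (default σ 1 ms) with a small
  AHP, on a flat rest or an exponential charging response (τ 20 ms,
  0.1 mV/pA), with analytic peak, width and slope recorded as truth.

What passing on this generator does **not** show: robustness to
bursting and network synchrony, electrode drift, non-stationary noise,
overlapping multi-unit waveforms, biophysical AP shapes, temperature
or K⁺ dependence, or plate/edge effects (the screen applies no plate
normalisation, matching the source protocol).

## Problem sizes and runtime

Rendered traces are memory-hungry (a full 288-channel, 3-phase, 300 s
plate is ~2.6 GB at float32), so rate-level studies use
`simulate_plate(render=False)` / `simulate_rate_table`, which draw the
identical spike counts without rendering. The test suite uses 12–48
channel rendered plates of 10–30 s for detector properties, 300 s
rate-level plates for screen statistics (20 compounds × 3 wells ×
12 electrodes), 100-seed Monte-Carlo loops for planted-hit recovery
and noisy IC50 recovery, and 200 seeds for LDH flag calibration; the
whole suite runs in about a minute on one CPU.

## Known limitations

- The detector reports multi-unit channel activity; there is no spike
  sorting, matching the screen's analysis level.
- The no-dose-dependence flag is a 1% SSE-improvement heuristic; very
  shallow true curves inside the tested range can trip it.
- `robust_z` is ±∞ when both MADs vanish with unequal medians; the
  screen flags rather than hides this (it occurs for channels with
  identical discrete counts, essentially only at tiny n or durations).
- The Boltzmann form's nonzero B(0) means vehicle wells show a small
  nominal "inhibition" for steep-slope/low-IC50 parameter combinations;
  fits restricted to positive concentrations are unaffected.
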