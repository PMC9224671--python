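# Methods

`atriosync` studies how features of surface-ECG P-waves (lead II) track
features of coronary-sinus (CS) local activation waves (LAWs) around
catheter ablation of paroxysmal atrial fibrillation. Because clinical
paired surface/intracardiac recordings of this kind are not publicly
deposited, the package is built around a synthetic cohort generator whose
statistical structure makes every stage of the analysis testable: the
generator's latent parameters are known, so recovery can be checked
exactly.

## The generative model

One patient-phase is a beat schedule plus two rendered channels.

**Heart period.** The master inter-beat interval (IBI) series is a
stationary AR(1) process, `IBI_i = mu + phi (IBI_{i-1} - mu) + eps_i`,
with marginal mean `mu = 800 ms`, marginal sd `sigma = 50 ms`,
`phi = 0.6`, floored at 200 ms. Defaults emulate resting sinus rhythm with
realistic short-range autocorrelation; 300 beats approximate a five-minute
recording at 1 kHz.

**Fiducials.** Each channel's activation peak is the master beat time plus
a constant conduction delay (CS: 30 ms) plus independent per-channel
Gaussian jitter (sd 40 ms by default). Jitter lumps together true local
conduction variability and delineation error; it is the mechanism that
masks raw cross-channel coupling. The activation peak is the IBI fiducial
throughout (the most jitter-robust landmark).

**Durations and the heart-rate-adjustment identity.** Cross-channel
coupling is placed on the cycle-fraction scale: per beat the pair of
normalized durations `(n_s, n_c)` — expressed as ms-equivalents at a
1000 ms cycle (surface 120 +/- 12, CS 80 +/- 8) — is drawn bivariate
normal with correlation `rho = 0.7`. The measured duration is
`D = n * IBI_ch / 1000` with `IBI_ch` the channel's own (jittered,
sample-quantized) interval. Heart-rate adjustment multiplies by
`sf = 1000 / IBI_ch` and is therefore the exact inverse of the generative
distortion: it recovers `n` to within one sample of quantization. This is
the minimal model in which heart-rate fluctuation genuinely masks a latent
coupling that the adjustment recovers; with 40 ms jitter the raw duration
correlation attenuates to ~0.58 while the adjusted one recovers ~0.70.

**Morphology.** P-waves are nonnegative raised cosines (maximum amplitude
equals peak-to-peak amplitude, as for positive lead-II P-waves; all slope
rates positive). LAWs are biphasic derivative-of-Gaussian wavelets with
the negative lobe first (early slope rates negative, peak-to-peak twice
the signed maximum), spanning `[c - 3s, c + 3s]` with the signed maximum
at `c + s`. Both shapes have closed-form ground-truth features. No
quantitative LAW morphology is established for the CS; the biphasic
wavelet is a modelling choice satisfying the qualitative sign constraints.

**Ectopic beats.** With probability `ectopic_rate` (default 2%, hard cap
4%) a beat is made premature: its fiducial is advanced by 30-40% of the
cycle, its duration scaled by 0.7 and amplitude by 0.6. Never the first
two or last beats, never two in a row.

**Noise.** Additive power-line sinusoid (0.02 mV at 50 Hz), baseline
wander (0.05 mV sinusoid at 0.25 Hz plus a scaled random walk), and white
noise (0.01 mV). Ventricular activity is not simulated, so no ventricular
cancellation stage exists; the analysis consumes delineated atrial
activations only.

**Phase effects.** Each procedure phase (pre-ablation, after left
pulmonary-vein isolation, post-ablation) applies multiplicative shifts:
duration x0.97 / x0.92 (LPVI / post), amplitude x0.95 / x0.90, mean heart
period x1.10 / x0.95 (heart rate falls during radio-frequency
application), IBI spread x1.3 / x0.8 (rate variability rises during and
falls after). Duration, amplitude and variability shifts carry a
per-patient lognormal spread (sd 2%, 2%, 10%) shared between channels, so
ablation-induced variation differs across patients. The heart-period
shift is deliberately patient-constant: the heart period is common-mode
across channels, so patient spread in it would add *shared* variance to
raw duration variation and obscure, rather than express, the confound the
adjustment corrects. With these defaults the cross-patient correlation of
per-patient percent change is consistently higher for adjusted than for
raw duration, because per-channel fiducial jitter noises raw medians
roughly three times more than adjusted ones.

**Seeds.** A master seed spawns per-patient child seeds
(`SeedSequence(master).generate_state(n_patients)`); each patient-phase
derives two independent streams (beat schedule, waveform noise) via
`SeedSequence(patient_seed, spawn_key=(phase_index, stream))`. Fiducial-
level results are therefore identical whether or not waveforms are
rendered, and identical configuration plus seed reproduces every output
byte for byte.

## Preprocessing

Filters are IIR designs applied forward-backward (zero phase) so fiducials
do not shift: a notch at the line frequency (quality factor 30) and a
4th-order Butterworth high-pass at 0.5 Hz for wander. Measured: >= 29 dB
line rejection, broadband RMS preserved within 10%, 5 Hz content within
1 dB.

Ectopic detection works on the fiducial interval series: beat `i` is
flagged when its preceding interval deviates more than 20% from the median
of the 11 surrounding intervals (itself excluded). A premature fiducial
shortens its own interval *and* lengthens the next (compensatory pause);
a long-interval flag immediately after a short-interval flag is attributed
to the same ectopic, so one premature beat yields one flag. Without this
suppression the false-positive rate at 4% prevalence would itself be ~4%.

Flagged beats are handled at the feature level: the flagged beat *and its
successor* (whose preceding cycle is the compensatory pause — the
normal-to-normal convention) are replaced by linear interpolation between
unflagged neighbours, in every feature column. Interpolating only the
flagged beat leaves the shared compensatory cycle in both channels and
inflates cross-channel duration correlations by +0.04..+0.08 above the
latent coupling. Flagged runs at a record edge are replaced by the nearest
defined value so lengths are preserved.

The delineator is a deliberately simple stand-in for expert-corrected
clinical delineation. Around each approximate peak it takes the smoothed
(8 ms) rectified amplitude relative to the local median baseline, finds
the sustained run above a threshold — 5% of the peak range or three times
the window-margin noise floor, whichever is larger — skipping
sub-threshold dips up to 15 ms (the inter-lobe zero crossing of a biphasic
wave). For monophasic surface humps the crossing is then corrected by
quadratic-edge extrapolation (`2 r / slope` outward; a smooth hump
vanishes quadratically at its foot, so the raw crossing is biased ~7% of
the duration inward); for biphasic CS waves the crossing itself is the
boundary, which is where their annotated bounds sit. Measured accuracy:
noise-free P-wave duration within 1 ms; median absolute duration error
3-4 ms at 20 dB SNR. Pipeline analyses use the generator's annotations by
default; the delineator serves flag-less or annotation-less input.

## Features

Per activation over the inclusive `[onset, offset]` window: duration (ms),
maximum signed amplitude, peak-to-peak amplitude, RMS (all mV), positive
area (trapezoidal, mV*ms), and signed slope rates from the onset to
5/10/20% of the duration and to the peak (mV/ms; percent points by
round-half-up, a degenerate rounding advanced one sample). Maximum
amplitude is the maximum *signed* sample — rectifying would hide the fact
that it coincides with peak-to-peak amplitude only for positive waves.

Heart-rate adjustment scales duration and area by `sf = 1000 / IBI` and
slope rates by `1 / sf`. The first activation has no preceding interval;
its adjusted fields are NaN and it is excluded from pairwise statistics
rather than borrowing the following interval.

Atrial rate variability per recording: SDNN (sample standard deviation,
ddof = 1, the HRV-literature convention), VARNN = SDNN^2, RMSSD. In the
synthetic model the measured SDNN exceeds the master-rhythm value because
per-channel fiducial jitter adds variance (sqrt(50^2 + 2*40^2) ~ 75 ms at
defaults), and RMSSD is jitter-dominated — so synthetic RMSSD transition
correlations are weak by construction.

## Statistics

Per recording, activations are paired one-to-one across channels by
nearest peak within +/-200 ms after removing the median inter-channel
delay; unmatched activations are dropped and counted. Pearson correlation
(reported in percent, two-sided t-test p) and simple linear regression
under seeded 10-fold cross-validation are computed per feature. The
cross-validated R^2 comes from pooled out-of-fold predictions (lower
variance than per-fold averaging at ~300 beats), is adjusted as
`1 - (1 - R^2)(n - 1)/(n - 2)` and floored at zero before conversion to
percent; the regression p-value is the full-data slope t-test, which for
one predictor is identical to the Pearson p-value — cross-validation
changes the effect size, not the test.

Cohort cells aggregate the 40 per-recording statistics by their median;
the Shapiro-Wilk test (alpha 0.05) switches to the mean only when the
per-recording values pass normality, and only from 8 recordings up (the
test has no power below that). The per-recording p-values are combined by
the same centre — a pragmatic, symmetric rule; Fisher combination or
pooled-activation correlation (available via the `pooled` option) are
alternatives with different operating characteristics. No multiplicity
correction is applied; the significance column is a plain `p < alpha`
threshold.

Ablation-induced variation per patient, feature and transition is the
percent change of the per-recording median,
`CV = (median_after / median_before - 1) * 100`, with rate-variability
summaries (one value per recording) used directly; a zero before-median
leaves it undefined and excluded. Cross-patient Pearson between the two
channels' variations gives the transition table.

## Cross-quadratic sample entropy

Both series are z-scored (ddof = 1). `A^m(r)` is the fraction of
cross-template pairs within Chebyshev distance `r`, with denominators
exactly the template counts `(N - m)(M - m)`, and `(N - m - 1)(M - m - 1)`
at length `m + 1`; a distance exactly `r` counts as a match. The value is
`-ln(A^{m+1}/A^m) + ln(2r)`, defaults `m = 1`, `r = 0.35`; the `ln(2r)`
term makes the value stable under changes of `r` (< 0.1 shift between
r = 0.2 and 0.35 on independent noise). Zero match probability at either
length yields NaN, never +/-inf. The implementation is chunked
vectorized numpy and is tested to agree with a literal double-loop
enumeration to 1e-12. For independent standard-normal series the expected
value is `-ln(erf(r/2)) + ln(2r)` (1.2757 at r = 0.35), since
`X - Y ~ N(0, 2)` gives a single-coordinate match probability of
`erf(r/2)` and templates of independent series match coordinate-wise
independently; this is the no-coupling reference against which shared
dynamics (lower values) are judged. Synthetic cohort medians sit near
this reference because most synthetic feature pairs share no serial
dynamics — matching the observation that paired-feature entropies in this
setting indicate weak nonlinear coupling.

## What the synthetic cohort does and does not show

The generator reproduces the *statistical* structure the analysis relies
on: autocorrelated heart period common to both channels, channel-specific
fiducial noise, cycle-fraction duration coupling, phase shifts with
patient spread, ectopy, and standard additive noise. It does not attempt
physiological waveform realism: no ventricular activity or QRST overlap,
no 12-lead geometry or volume conduction, no atrial-fibrillation f-waves,
no multi-electrode CS catheter (one CS channel is emitted, so no
channel-selection rule), and the duration-cycle proportionality is exact
by construction rather than an empirical restitution curve. Passing tests
therefore demonstrate that the pipeline measures what it claims on data
with this structure — not that clinical recordings have this structure.

## Problem sizes and numerical choices

Cohort-level checks run at the study scale (40 patients x 300 beats),
with 10-50 seed replicates for distribution-level properties and 3-10
patients for waveform-level round trips; the independent-Gaussian entropy
limit uses 20 pairs of length 5000. Tolerances follow from the mechanism
being checked: 1e-12 against the enumeration oracle (pure floating-point
reordering), one fiducial sample for generator round trips, sampling-error
bands (e.g. +/-0.07 on a correlation recovered from 40 x 300 pairs)
elsewhere. Ties and degenerate cases: zero-variance series are errors for
correlation and normalization; flat delineation windows are skipped with a
warning; the cross-validated R^2 is floored at zero; undefined entropy
propagates as missing.
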