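# atriosync

Surface P-wave vs coronary-sinus electrogram feature coupling around
catheter ablation of atrial fibrillation.

During pulmonary-vein isolation, a stationary coronary-sinus (CS) catheter
records local activation waves (LAWs) while the surface ECG records
P-waves — two views of the same atrial depolarization. A natural question
for electrophysiologists and biosignal researchers is how well per-beat CS
features track the established surface P-wave markers of atrial substrate,
and how ablation changes that relationship. The catch is heart-rate
fluctuation: interval-dependent features ride the cardiac cycle, and
channel-specific timing noise masks whatever coupling exists. `atriosync`
implements this analysis end to end, centred on three ingredients:

- **Heart-rate adjustment (HRA).** Each interval-dependent feature of
  activation *i* is scaled by `sf_i = 1000 / IBI_i` (durations and areas
  multiplied, slope rates divided), where `IBI_i` is the inter-beat
  interval in ms. This transforms durations onto a cycle-fraction scale
  and unmasks cross-channel coupling hidden by rate fluctuation.
- **Ablation-induced variation.** Per patient, feature and procedure
  transition, `CV = (median_after / median_before − 1) × 100 (%)`,
  correlated across patients between the surface and invasive channels.
- **Cross-quadratic sample entropy (CQSE).** For z-scored series X, Y,
  `CQSE(m, r) = −ln(A^{m+1}(r) / A^m(r)) + ln(2r)` with `A^m` the
  cross-template match probability at Chebyshev tolerance `r` (defaults
  `m = 1`, `r = 0.35`); the `ln(2r)` correction makes values comparable
  across tolerances. Low values indicate shared nonlinear dynamics; two
  independent Gaussian series give `−ln(erf(r/2)) + ln(2r) ≈ 1.28`.

Around these sit per-activation morphology features (duration, maximum /
peak-to-peak / RMS amplitude, positive area, slope rates at 5/10/20% and
the peak), atrial-rate-variability summaries (SDNN, VARNN, RMSSD) computed
on activation intervals, Pearson and 10-fold cross-validated regression
statistics with Shapiro–Wilk-gated cohort aggregation, and standard
preprocessing (zero-phase notch and high-pass filters, ectopic detection
and feature-level interpolation, a threshold delineator).

Paired clinical recordings of this kind are not publicly deposited, so the
package includes a first-class synthetic cohort generator producing paired
1 kHz surface/CS recordings with ground-truth annotations: AR(1) heart
period, per-channel fiducial jitter, duration coupling on the
cycle-fraction scale (so HRA is the exact inverse of the generative
distortion), ectopic beats, phase effects of ablation, and line/wander/
broadband noise. Every stage is tested against the generator's latent
parameters; see `docs/methods.md` for the model and its limits.

## Worked example

```python
from atriosync import CohortConfig, run_study

res = run_study(CohortConfig(seed=1))   # 40 patients, 3 phases, 300 beats

p = res.tables["pearson"]
print(p[p.feature.isin(["duration", "hra_duration", "ampmax"])]
      .pivot(index="feature", columns="phase", values="statistic")
      [["pre", "lpvi", "post"]].round(1))
```

```
phase          pre  lpvi  post
feature
ampmax         0.7   2.3   0.2
duration      57.6  65.1  54.1
hra_duration  70.7  70.1  69.7
```

Each cell is the cohort median of per-recording Pearson correlations (%)
between paired surface and CS features. Uncoupled amplitudes sit at zero;
raw duration is attenuated to ~58% by heart-rate fluctuation and fiducial
jitter; heart-rate adjustment recovers the latent coupling of 70%
programmed into the generator — the central masking/unmasking effect.
The same contrast appears across ablation transitions (cross-patient
correlation of CV, `res.tables["transitions"]`) and per-recording CQSE
medians sit near the independent-noise reference
(`res.tables["cqse_summary"]`, ~1.25), indicating no extra nonlinear
coupling beyond the linear structure built into the cohort.

The same analysis is available from the shell:

```sh
atriosync simulate --config cohort.yaml --out cohort/   # write recordings
atriosync run --seed 1 --out results/ --no-plots        # tables as CSV
```

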