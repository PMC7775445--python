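# Methods

This note documents the scientific model, the measurement definitions, the
statistical procedures and the numerical conventions implemented by
`salience_cpt`, together with the known limitations of the simulation.

## 1. Task design

The task is a *salience-extended 'not-X' continuous performance task*: a
stream of single stimuli requiring a button press to every stimulus except
the letter X.

| Parameter | Default | Notes |
|---|---|---|
| Blocks × trials | 8 × 100 | 800 trials total |
| NoGo ('X') per block | 25% | 200 total |
| SalientGo (red square) per block | 10% | 80 total; 13.33% of Go trials |
| StandardGo (letters, not X) | remainder | 520 total |
| Stimulus duration | 150 ms | |
| Inter-stimulus interval | 1500 ms | trial duration 1650 ms |
| Response window | [200, 1500] ms, closed | relative to stimulus onset |

Special trials (NoGo, SalientGo) are spaced: at least 2 StandardGo trials
between consecutive specials of the same condition and at least 1 between
specials of different conditions, enforced **across block boundaries**.
The generator places specials block by block under these constraints; a
placement dead-end (possible because slack is consumed randomly) triggers a
whole-sequence restart from the continuing RNG stream, so any feasible
configuration is eventually generated and the output remains a pure function
of the seed. `validate_sequence` independently re-checks composition,
separation, onsets and stimulus coding.

## 2. Synthetic cohort

Each subject is a vector of latent parameters drawn from a Gaussian copula:
correlated standard normals are transformed through per-parameter marginals
(normal, clipped; means and SDs chosen a priori to match published
descriptive statistics for typically-developing children of this age), so
target Pearson correlations between the ADHD symptom index and each latent
parameter can be injected directly. The symptom score is
`clip(round(5.32 + 4.36·g), 0, 30)`; covariates are age (10.7 ± 0.53 y),
sex, and a raw IQ-test score. `EffectConfig.null()` zeroes every injected
correlation for type-I simulations.

Latent parameters cover behavior (standard-Go RT mean and SD, salient-Go RT
shift and SD, false-alarm probability on NoGo, miss probability) and, per
ERP component, the subject's mean amplitude, mean latency, and
trial-to-trial amplitude/latency SDs.

## 3. EEG forward model

Continuous EEG (default 200 Hz, 8 channels incl. M1/M2) is a sum of
stimulus-locked Gaussian components and noise:

- **P1** (all conditions) and **P2** (NoGo) as fixed early components; a
  **standard P3** present in *all* conditions (it cancels in difference
  waves).
- **inhibition-P3** (NoGo only), **salience-P3** and **salience-N2**
  (SalientGo only), whose per-trial amplitude and latency are drawn from the
  subject's latent means and SDs (latencies clipped to physiological
  ranges). Scalp topography uses fixed per-channel weights (posterior
  maximum for P3, frontal for N2).
- Noise: 1/f ("pink") noise of 6 µV SD plus 4 µV white noise per channel,
  chosen a priori; component bumps are truncated at ±4σ.

Behavior is simulated consistently with the same latents: shifted-lognormal
RTs (150 ms shift), misses with probability `miss_p`, NoGo false alarms
with probability `fa_p`.

## 4. Preprocessing

Common-average reference (mastoids excluded) → optional downsampling (with
event-sample rescaling) → 0.1–30 Hz band-pass (FIR, via MNE) → re-reference
to linked mastoids → epoching −200…+895 ms around stimulus onsets (events
too close to the recording edge are dropped with a warning) → baseline
correction over [−200, 0] ms. All window selections use closed intervals
with edges snapped to the nearest sample. An `ica_hook` slot allows
artifact-correction callables to be inserted; the synthetic data need none.

## 5. ERP measurement

All component effects are quantified on **difference waves** (inhibition:
NoGo − StandardGo; salience: SalientGo − StandardGo), only correct trials
included (hits for Go, correct inhibitions for NoGo):

| Component | Site | Window | Polarity |
|---|---|---|---|
| inhibition-P3 | POz (replication: Pz) | 300–600 ms | positive |
| salience-P3 | POz (replication: Pz) | 350–600 ms | positive |
| salience-N2 | Fz | 250–350 ms | negative |

- **Signed-area amplitude** (µV·ms): integral of the polarity-consistent
  part of the waveform in the window. The waveform is modelled as
  piecewise-linear between samples and rectified **after** interpolation:
  exact zero-crossing nodes are inserted before clipping, so the area is
  exact for the interpolated waveform rather than a sample-grid
  approximation. N2 areas are reported as positive magnitudes.
- **50% fractional-area latency** (ms): the time at which the cumulative
  rectified area reaches half the window total. The cumulative area of a
  piecewise-linear signal is piecewise-quadratic; the crossing is solved in
  closed form within the bracketing segment. Windows with zero
  polarity-consistent area yield NaN (undefined latency), which is excluded
  from latency statistics only.
- **Trial-to-trial variability**: the SD (ddof = 1) of per-trial amplitudes
  and latencies of the *critical* condition at the component electrode (a
  per-trial difference wave does not exist). An optional low-pass
  (`smooth_hz`) can be applied to single trials before measurement; it is
  off by default.

Behavioral measures: RT mean/SD per condition from hits inside the closed
response window; commission ratio = FA / (FA + correct inhibitions);
omission ratio = misses / Go trials; salience RT effect = salient mean RT −
standard mean RT.

## 6. Statistical battery

For each of the 20 (component, site, measure) targets — 12 primary, 8 Pz
replications — the battery correlates the measure with the ADHD symptom
index, partialling out age, sex and IQ:

1. pairwise deletion of records with missing values (logged);
2. single-pass exclusion of observations beyond 3 SD of either variable;
3. Shapiro–Wilk gate (p < .05 on either variable → Spearman: *all*
   variables rank-transformed, including covariates; otherwise Pearson);
4. partial correlation by residualization on the covariates (with
   intercept); two-tailed p from t with df = n − 2 − k;
5. significance at α = 0.05 uncorrected and at the Bonferroni-corrected
   threshold α/4 = 0.0125 (four measures per component family).

A degenerate-residual guard returns r = 0, p = 1 when a variable is fully
explained by the covariates. Power analysis uses the Fisher-z
approximation `r_min = tanh((z_{1−α/2} + z_power)/√(n−3))`; at n = 31 the
minimum detectable correlation at 80% power is 0.48.

## 7. Reproducibility

A single run seed feeds `numpy.random.SeedSequence`, whose
`generate_state(1 + 3·n_subjects)` vector (masked to 31 bits) is consumed
as `[profiles, subj0-sequence, subj0-eeg, subj0-behavior, subj1-…]`.
Identical config + seed therefore yields byte-identical output tables; the
run manifest records the package version, the full config and its SHA-256.

## 8. Known limitations

- **Single-trial amplitude-SD attenuation.** Per-trial rectified-area
  amplitudes carry a noise floor: rectifying a waveform whose window
  contains ~1000 µV·ms of low-frequency noise area makes the *measured*
  trial-to-trial amplitude SD depend strongly on the subject's mean
  amplitude and only weakly on the latent amplitude jitter (the jitter
  signal is ~370 µV·ms against that floor). Consequently, correlations
  injected on the latent amplitude SD are substantially attenuated in the
  measured analogue (e.g., an injected r = −0.51 for the salience-P3
  amplitude SD is recovered around −0.33 at n = 200), while mean-amplitude
  and latency-SD effects recover within sampling error. Low-pass smoothing
  of single trials does not remove the floor (it sits below 15 Hz), and
  sub-averaging does not change the signal-to-floor ratio. Interpreting
  amplitude-SD correlations from area measures therefore requires a
  noise-floor correction or a different single-trial estimator; we report
  the attenuation rather than re-tune the noise model.
- Single-trial **latency** SD is likewise noise-inflated but preserves
  rank order well (latent-to-measured correlation ≈ 0.5 at default noise),
  so injected latency-SD effects recover within sampling error.
- The forward model is stationary within a session: no fatigue, drift,
  ocular/muscle artifacts, or learning effects; the `ica_hook` exists for
  real-data use but is unexercised by the simulation.
- The copula injects *linear* dependence on a single symptom score;
  nonlinear or subgroup structure is out of scope.
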