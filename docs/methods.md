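# Methods

This document records the generative model behind `eegfatigue.synth`, the
numerical conventions of the analysis pipeline, and the experimental designs
used by the acceptance tests.

## 1. Synthetic session model

A session is a deterministic function of a `SimulationConfig` and a condition
(`"mi"` motor imagery with real feedback, `"control"` sham feedback).

### Protocol schedule

| stage | default |
| --- | --- |
| pre-session rest | eyes-closed then eyes-open, `pre_post_rest_s` = 120 s each |
| VR blocks | `block_count` = 3 blocks of `trials_per_block` = 25 trials |
| trial | 20 s rest (`rest_trial_s`) → motor imagery ≤ 20 s (`mi_max_s`, success needs ≥ 5 s, `mi_success_min_s`) → 2–7 s pause (`pause_range_s`) |
| post-session rest | eyes-closed then eyes-open, same duration |

Control sessions draw sham trial outcomes with per-block success
probabilities `control_success_probs` = (0.30, 0.40, 0.35) and plant no ERD.

### Signal model (per channel, μV)

* Aperiodic background: Gaussian noise spectrally shaped to `1/f^β`,
  β = `background_exponent` = 1.3, RMS `noise_rms` = 10 μV.
* Posterior alpha: `alpha_freq` = 10 Hz, bandwidth 2 Hz, base amplitude
  `alpha_amplitude` = 6 μV with a posterior spatial profile (peaks at
  O1/O2).  The envelope is `(1 + alpha_fatigue_gain · f(t))`, scaled by
  `ec_eo_ratio` = 2 during eyes-closed rest;
  `alpha_fatigue_gain` = 0.3 is the planted fatigue effect.
* Sensorimotor μ: `mu_freq` = 10.75 Hz, amplitude `mu_amplitude` = 4 μV on a
  central spatial profile.  During successful imagery the envelope is
  suppressed by up to `erd_depth` = 0.5 (smoothed ERD mask); after the
  session the amplitude is raised by `mu_post_gain` = 0.25, modelling
  training-induced strengthening of the rhythm.
* Fatigue ground truth `f(t)`: 0 before the first block, rises during VR
  blocks, drops by `recovery_fraction` = 0.2 at each between-block rest, and
  is normalized to reach exactly 1.0 at the end of the last block, held
  constant afterwards.
* Artifacts (`inject_artifacts`): blinks (frontal, ~10/min) and EMG bursts
  (~4/min); injection is conservative — the stored event waveforms added back
  onto the clean signal reproduce the artifacted signal bit-for-bit.
* Questionnaires: 7-point items whose noiseless response is an affine
  function of the stage fatigue level (e.g. `mental_fatigue` slope +0.40·6,
  `motivation` slope −0.25·6), quantized after adding Gaussian noise
  (`noise_sd` = 0.6).  Stage levels come from `stage_fatigue`: pre, end of
  each block, post.

## 2. Pipeline conventions

### Preprocessing

Common-average reference, 4th-order Butterworth high-pass at 1.5 Hz
(`sosfiltfilt`, zero phase), segmentation into 2 s epochs with 0.5 s step
(half-open windows, trailing partial epochs dropped), 50 Hz IIR notch
(Q = 30) applied per epoch, then amplitude (>100 μV) and gradient
(>50 μV/sample) flagging.  Flagging never modifies data.

### IRASA

The fractal (aperiodic) component is the median over
h ∈ {1.1, 1.15, …, 1.9} of the geometric mean of the spectra of the
h-upsampled and h-downsampled signal.  Two conventions matter:

1. **Original-rate evaluation.** The resampled signals' spectra are computed
   at the *original* sampling rate: oscillatory peaks then shift by a factor
   h while a power law is invariant, which is what lets the median remove
   oscillations.  (Evaluating at the nominally correct resampled rate makes
   all spectra identical and the harmonic collapses to zero.)
2. **Amplitude spectra.** IRASA runs on Hann amplitude (root-power) spectral
   densities, and the harmonic is defined as `raw − fractal`, so
   `fractal + harmonic = raw` holds exactly in amplitude mode; a `power`
   mode squares the amplitude spectra first.

The default `fft` resampling path exploits that `scipy.signal.resample` is a
linear map on rfft coefficients: away from spectral edges the resampled
windowed spectrum is `sqrt(num/n)` times the raw one, and only ≤ 3 edge bins
per direction need exact evaluation.  This path agrees with the time-domain
oracle (`scipy.signal.resample` + periodogram) to ~1e-15 and is ~17× faster;
a `poly` path (`scipy.signal.resample_poly`) is kept as a cross-check.

Features are the harmonic amplitudes restricted to 5–20 Hz:
a tensor of epochs × frequencies × channels.

### PARAFAC and μ-atom deflation

Rank-R PARAFAC by ALS with unit-norm frequency/space factors and magnitude
absorbed into the scores.  The first restart is initialized from the leading
singular vectors of each unfolding (HOSVD): purely random initializations can
converge to a two-factor degenerate local minimum in which two components
collapse onto the strongest true factor.  Remaining restarts are random; the
best final fit wins.

The μ atom is the PARAFAC component (rank 3 on the tensor restricted to the
10 central electrodes FC5/FC1/FC2/FC6/C3/C4/CP5/CP1/CP2/CP6) whose frequency
peak is closest to 10.75 Hz.  Deflation zero-pads its spatial weights to the
full montage and removes the least-squares rank-1 contribution
`t_i = ⟨X_i, P⟩ / ⟨P, P⟩`, `X_i ← X_i − t_i P`; it is exact on rank-1 input,
idempotent, and never increases the Frobenius norm.

### N-PLS and LDA

Tri-PLS1: per factor the frequency/space weight pair is the leading singular
pair of `Z = Σ_i y_i X_i` on centered data; X is deflated by the rank-1
factor contribution and y by its fitted part between factors; the regression
coefficients solve `y ≈ T B` by least squares.  Constant labels raise;
requests beyond the effective rank truncate with a warning.

LDA uses the classical unbiased pooled covariance (scatter / (n−2)) shrunk
toward its diagonal (`(1−λ)S + λ diag S`, λ = 1e-4).  Note scikit-learn
pools with 1/n; the test suite validates against scikit-learn after
rescaling.

### Cross-validation

Epochs overlap in time, so naive random folds leak samples between train and
test.  `stratified_folds` splits each stratum's time-ordered epochs into k
contiguous chunks and assigns whole chunks to folds (seeded).  Strata are
classes, or (class × group) pairs when a `groups` covariate is passed — the
eyes-closed/eyes-open condition must be a group because its alpha ratio (2×)
exceeds the planted fatigue gain (1.3×) and would otherwise confound folds.

Binomial chance bands are only valid for *non-overlapping* epochs
(step = epoch length); overlapping epochs correlate held-out decisions and
inflate the null accuracy variance.

### Trajectory

LDA posteriors over all epochs are smoothed with a centered 100-epoch moving
average (edge-truncated), summarized into pre + 3 points per block + post
stage means, and the slope `p1` of the line `y = p1·x + p2` over the stage
index is the fatigue-trend summary.

## 3. Acceptance-test designs

The acceptance criteria are property-based; Monte-Carlo seed counts are kept
at full size while session lengths are scaled down (125 Hz, 2 blocks, fewer
trials) to fit the runtime budget.  Planted effect sizes, noise levels,
thresholds and analysis bands are the generator/pipeline defaults throughout.

| criterion | design |
| --- | --- |
| N-PLS oracle | 50 seeds, 30×8×6 tensors, first factor vs SVD of `Z`, covariance beats 1000 random weight pairs |
| PARAFAC recovery | 100 seeds, rank-3 20×15×10 at 20 dB SNR, greedy factor matching, congruence ≥ 0.95 per mode in ≥ 95 seeds |
| deflation | exact rank-1 removal ≤ 1e-10, idempotence ≤ 1e-8, norm non-increase |
| μ-specificity | 2 blocks × 8 trials, 60 s rests; μ atom from MI epochs (rank 3, central 10); central-10 spatial mass of an F=2 N-PLS model on rest epochs drops after deflation in ≥ 45/50 seeds.  F=2 because higher factors chase noise with unstable topographies |
| IRASA separation | 100 seeds; pure 1/f, 8 non-overlapping 2 s epochs × 32 channels, epoch-averaged harmonic/raw band power median ≤ 5%; with a planted 10 Hz oscillator the epoch-averaged harmonic argmax is within 10 ± 0.5 Hz in every seed |
| effect/null calibration | 2 blocks × 6 trials, 300 s rests, eyes-closed pre/post epochs only, artifacts injected and flagged epochs removed, k=5, F=4; detection above the binomial 97.5th percentile in ≥ 19/20 sessions.  Null sets *both* `alpha_fatigue_gain=0` and `mu_post_gain=0`; the *median* accuracy of 5 null sessions must lie inside the binomial 95% band (a single session has an intrinsic 5% false-alarm rate; the median of five has ~1.6e-4) |
| trajectory | 2 blocks × 4 trials, 120 s rests; `p1 > 0` in ≥ 19/20 seeds; artifact injection changes ≤ 10% of smoothed class assignments on 5 seeds |
| metrics | PAM closed form vs shoelace oracle, hand confusion arithmetic, mid-rank Spearman oracle |
| questionnaire | same sessions as trajectory, 100 seeds; Spearman(mental fatigue, stage estimates) median > 0 and Spearman(motivation, ·) median < 0, `nanmedian` because noiseless links can yield constant items |

## 4. Scope and limitations of the generator

The generator plants exactly the structure the pipeline is designed to
detect (stationary 1/f background, band-limited alpha/μ oscillators with
low-dimensional spatial profiles, multiplicative fatigue envelopes).  It does
not model volume-conduction mixing beyond the fixed spatial profiles,
non-stationary background spectra, inter-subject variability, or realistic
artifact morphologies beyond damped blink/EMG templates.  Quantities computed
on it (accuracies, PAM, slopes) characterize the pipeline under the planted
model, not human EEG.
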