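# Methods

This note documents the model, the defaults and the numerical and design
choices of the `babytrf` package, including what the synthetic-cohort tests
do and do not demonstrate.

## 1. Stimulus features

- **S — acoustic spectrogram.** The audio is band-passed into 8 bands
  between 250 and 8000 Hz whose edges are equally spaced along the cochlear
  position axis of the Greenwood map `F(x) = A(10^{ax} − k)` with the
  canonical human constants A = 165.4, a = 2.1, k = 0.88.  Each band's
  Hilbert envelope is anti-alias low-passed at 0.45·fs_out and resampled to
  the analysis rate (50 Hz by default).
- **D — envelope derivative.** The broadband envelope is the row sum of S;
  D is its half-wave-rectified first difference (onset emphasis), with
  D[0] = 0.
- **F — phonetic features.** Time-aligned phonemes (Praat long-format
  TextGrid) are mapped to 14 binary articulatory features (voiced/unvoiced
  consonant, plosive, fricative, nasal, strident, labial, coronal, dorsal,
  anterior, front, back, high, low) via a shipped ARPAbet-style lookup
  table.  Each phoneme contributes rectangular pulses over its interval
  (half-open sample spans, minimum one sample); overlaps are resolved by
  logical OR, so F stays binary.  The lookup table is a reconstruction of
  the standard articulatory convention, not a copy of any published
  electronic resource.
- **V — visual motion.** Mean absolute inter-frame luminance difference,
  resampled to the analysis rate; a nuisance regressor for audiovisual
  stimuli.

## 2. EEG conditioning

Order of operations (each trial, after averaging repetitions):
drop facial channels → zero-phase order-2 Butterworth low-pass (8 Hz) →
high-pass (0.1 Hz) → resample to 50 Hz → bad-channel interpolation →
mastoid re-reference (and mastoid removal).  With the default 64-channel
montage (58 scalp + 2 mastoids + 4 facial) this yields 58 analysis
channels.

- Filters are applied forward–backward (`sosfiltfilt`), so the effective
  magnitude response is the squared Butterworth response and the phase
  delay is zero.
- Bad channels: |z| > 3 on kurtosis or log-variance across channels;
  flagged channels are replaced by inverse-distance-weighted averages of
  their 4 nearest montage neighbours.  If more than half the channels are
  flagged the recording is rejected rather than repaired.
- Ground-truth EEG: for each trial and band, the grand average over scalp
  channels and participants, then band-filtered (average-then-filter; with
  a zero-phase linear filter the order does not matter, and averaging first
  is cheaper).
- ERP SNR control: power in the 0.5 s after the first word onset divided by
  power in the 0.5 s before; its age effect is tested to rule out trivial
  SNR explanations for developmental effects.

## 3. TRF estimation

The forward model and estimator are the package's core:

- Lagged design: lags span −100…+500 ms (31 lags at 50 Hz; lag index
  rounds half away from zero).  Columns are feature-major; out-of-range
  samples are zero-padded.
- Ridge: `w = (XᵀX + λM)⁻¹XᵀY` via Cholesky, intercept unpenalised.
  Features and responses are z-scored on the training folds (implemented
  algebraically on cached sufficient statistics); returned weights are
  converted back to input units.  `M` is the identity (default) or the
  Gram of the second-difference operator per feature ("derivative" —
  penalises curvature, i.e. enforces smooth kernels).
- Cross-validation: leave-one-trial-out outer loop; inside each training
  fold, a nested leave-one-out loop picks λ from 10⁻²…10⁶ (ties go to the
  smaller λ).  Per-trial Gram/cross-product caches plus one
  eigendecomposition per training fold make all λ solves cheap, and shared
  stimuli across participants share their lagged designs.
- Scoring: Pearson correlation between the predicted EEG (per channel) and
  the cohort ground-truth trace of the held-out trial, averaged over folds.
- FS−S gain: mean-channel r of the full model (S, D, V, F) minus the
  reduced model (S, D, V), both cross-validated with their own λ tuning.

## 4. Statistical battery

Assumption screening (Shapiro–Wilk per condition; Mauchly for sphericity)
routes each subjects-×-conditions table to rmANOVA, rmANOVA with
Greenhouse–Geisser correction, or Friedman (paired Wilcoxon when only two
conditions, since Friedman needs k ≥ 3).  The Wilcoxon signed-rank p-value
is exact by full 2ⁿ sign enumeration for n ≤ 15 nonzero differences and a
continuity-corrected normal approximation beyond.  GG ε is
`tr(Sc)²/((k−1)ΣSc²)` on the double-centred condition covariance, clipped
to [1/(k−1), 1]; Mauchly uses k−1 orthonormal contrasts (its p is the
first-order chi-square approximation).  Note the Friedman statistic is
reported with df = k−1.  Post-hoc gain tests (one-sample per session,
paired between sessions) are FDR-corrected (Benjamini–Hochberg) as one
family.  The topography analysis bootstraps groups of 17 participants
(100 iterations) and correlates the average TRF-F channel map with the
oldest session's mean map.

The rmANOVA/GG/Mauchly/exact-Wilcoxon implementations are in-package
(their exact behaviour is part of the deliverable); scipy and statsmodels
supply the standard primitives (Friedman, Shapiro–Wilk, approximate
Wilcoxon, FDR), and pingouin is used in the test suite as an independent
oracle only.

## 5. Synthetic cohort generator

- Phoneme sequences tile each trial with log-normal durations (mean 1/rate,
  rate 8 s⁻¹).
- Spectral templates per phoneme are driven by the phoneme's articulatory
  feature vector, so phonemes sharing features have similar spectra — the
  **acoustic–phonetic confound**.  `confound_strength` sets the
  per-instance spectral jitter (1 − strength), smoothly interpolating
  between independent S/F (0) and S fully determined by phoneme identity
  (1).  A multiplicative prosodic envelope and temporal smoothing complete
  S; D derives from S; V is independent smoothed noise.
- EEG is the exact lagged convolution of S and F with smooth hidden kernels
  (2–3 Gaussian bumps × smooth topography per feature) plus mixed 1/f and
  white noise scaled relative to the mean scalp signal SD.  Mastoids carry
  a small common-signal share; facial channels are noise-only.
- The longitudinal cohort shares stimuli across participants and sessions;
  each participant's kernels are smooth jitters of cohort kernels; the
  phonetic kernels are scaled by the session gain (defaults 0 → 0.5 → 1.0
  for 4, 7 and 11 months); repetitions ≥ 3 can drop out at random.
- All randomness flows from one master seed through `SeedSequence`
  spawning.  The hidden truth (kernels, gains) is returned separately and
  is never written into the dataset payload.

**Scope.**  The generator validates the *estimator*, not infant
neurophysiology: passing tests show the pipeline recovers planted effects
and bookkeeping is correct.  They do not show that real infant EEG has
these properties, that the noise model matches real artifacts, or that the
statistic's behaviour on real data equals its behaviour here (see §7).

## 6. Problem sizes, defaults and design decisions

- **Scaled experiment sizes.**  Repeated-cohort experiments
  (`babytrf.calibration`) run at a 20–25 Hz analysis rate, 3 trials × 20 s
  and 8 scalp channels so hundreds of cohorts fit desk-scale compute.
  These are package choices; all defaults (50 Hz, 18 trials, 64 channels,
  47 participants) remain study-scale.
- **Derivative penalty for kernel inspection.**  Prediction scoring
  defaults to the identity penalty.  Kernel-recovery fits use the
  smoothness (second-derivative) penalty with λ chosen by the package's
  own tuner: the generator's kernels — like physiological TRFs — are
  smooth, and the smoothness prior is the standard choice when weights are
  interpreted.  Recovery at noise SD = signal SD reaches r ≈ 0.97 (S) and
  r ≈ 0.9 (F); the identity penalty leaves r(F) ≈ 0.85.
- **Greenwood constants.**  The canonical human map
  `F(x) = A(10^{ax} − k)` is used.
- **Channel bookkeeping.**  The generator's default montage is 64 channels
  (58 scalp + 2 mastoids + 4 facial), matching the 64 → 58 preprocessing
  contract.
- **Per-trial bad-channel statistics.**  Kurtosis/variance z-scores are
  computed per recording (after repetition averaging), not per session.
- **Friedman for k = 2** degenerates; the pipeline substitutes the paired
  Wilcoxon test there.
- **TextGrid parser** is hand-written (long format, interval tiers) since
  no TextGrid library is a dependency; parse errors report line numbers.

## 7. Known limitation: the FS−S statistic is not null-calibrated

Under a true null (phonetic kernels absent, acoustic confound present),
the FS−S gain is **systematically negative**, for two reasons:

1. at small λ, the 14 × L extra phonetic columns fit noise, lowering the
   full model's held-out correlation;
2. at large λ, ridge shrinkage under-partials the S↔F shared variance, so
   the full model misallocates weight between the correlated S and F
   blocks, again lowering its correlation.

Across generator scales (3×20 s to 6×75 s per participant) the bias is
8–11× the between-participant spread of the gain, approximately
scale-invariantly; matched λ for the nested pair, fixed λ from 0.1 to 10⁶,
and noise SD up to 10× signal do not change the sign pattern.
Consequently a two-tailed one-sample Wilcoxon on null-cohort gains rejects
in essentially every cohort — in the negative direction — rather than at
the nominal 5%.  The corresponding acceptance test asserts the nominal
binomial band and **fails honestly**; it was not widened to fit.

Practical implications: (a) a *negative* FS−S gain is not evidence against
phonetic encoding, only a gain reliably above the null's negative bias is
informative; (b) between-session *contrasts* of the gain are unaffected,
because the bias is common to all sessions — which is why the age-effect
recovery (planted gains 0 → 0.5 → 1.0) is detected in 100% of replicate
cohorts; (c) for calibrated single-session inference, a permutation or
simulated null reference should be preferred over the zero-median test.
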