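# Methods

This note documents the models, estimators and numerical choices behind
screamkit, and what its synthetic-data tests do and do not establish about
real recordings.

## Synthetic scream model

A scream is synthesized as a harmonic stack on a pseudo-fundamental
trajectory f0(t) = `base_freq` + `freq_slope`·t, with per-harmonic 1/k
amplitude roll-off (harmonics above Nyquist dropped), mixed with broadband
noise and shaped by a raised-cosine attack/decay envelope.  Tonal and noise
components are normalized to unit power before mixing, so `noise_mix` is
exactly the broadband energy share.  The clip's peak amplitude equals
`amplitude` (≤ 1, no clipping).

**Noise colour.** By default the noise is spectrally matched to the
harmonic-stack envelope (a sum of Gaussians, sd = 0.35·f0, centred on the
harmonics with 1/k weights).  The scientific rationale is physical —
turbulent (aspiration) noise passes the same vocal-tract filter as the voiced
source — and statistical: flat noise would mechanically drag the frequency
quartiles toward the band centre as `noise_mix` rises, so a severity
manipulation aimed at entropy would confound every frequency-distribution
parameter.  With matched noise, entropy increases monotonically with
`noise_mix` while Q50/IQR stay approximately stable over the study's noise
range.  `noise_shape="white"` is available and is what the entropy anchor
(white noise → 1) refers to.

**Non-linear phenomena.** Four injectable source irregularities, all active
on the central 30–80% of the call: a frequency jump (f0 multiplied by
1 + `jump_frac`), sub-harmonics (a component at f0/2 at `subharmonic_db`
relative to the fundamental), bi-phonation (an independent second voice at a
fixed, non-harmonic ratio to f0 — it tracks f0's drift, as a second source
filtered by the same tract would), and deterministic chaos, approximated by
replacing the tonal part of a segment with full-depth noise.  The chaos
stand-in is sufficient for entropy-based detection; no Lyapunov machinery is
attempted.

**Per-call frequency drift** is drawn as a *total* excursion
(`freq_drift_sd`, default 500 Hz) and converted to a slope by dividing by the
call's duration.  Drawing a slope directly would make longer calls smear
their spectra more, coupling every spectral parameter to duration — an
estimator artefact that would masquerade as a social-role effect whenever
role affects duration.

## Study-level generator

The default `StudyConfig` reproduces the structure of the field dataset the
pipeline targets: 26 callers, exactly 374 analysable screams in 119 bouts and
95 events (allocation by conditioned multinomials, so the totals are exact at
any seed), one recording per event.  Within an event, consecutive bouts
change the signaller's role or the conflict severity — the definition of a
bout boundary — so bout grouping is genuinely exercised.  Focal callers are
assigned so every caller appears at least once, with remaining events drawn
with log-normal activity weights (`caller_activity_sd`, default 1.0),
mirroring the strongly unequal per-individual call counts of ad-libitum field
sampling; this is also what makes a balanced crossed design feasible for a
handful of high-activity callers, as in real datasets.

Configured effects (defaults are the study conditions; all are switchable):

| parameter | default | meaning |
|---|---|---|
| `between_sd` / `within_sd` | 300 / 100 Hz | caller signature spread vs within-caller spread (ratio 3: identity recoverable at call level) |
| `victim_duration_factor` | 1.5 | victims' scream-duration ratio |
| `victim_q50_shift` | +200 Hz | victims' frequency shift |
| `noise_mix_mild`, `severe_entropy_shift` | 0.25, +0.20 | severity's noisiness manipulation |
| `mild_nlp_prob` / `severe_nlp_prob` | 0.15 / 0.45 | per-scream NLP injection probability |
| `severe_rate_factor` | 0.6 | scream-rate ratio in severe conflicts |
| `mean_interval` | 0.5 s (truncated ≥ 0.3 s) | inter-scream interval within a bout |
| `support_prob_aggressor` / `_victim` | 0.396 / 0.048 | per-bout support probability by role |
| `support_prob_severe_multiplier` | 2.0 | severe-conflict odds multiplier on support |
| `support_caller_sd` | 0.3 | caller random effect on the support logit |

Within-caller spread, activity spread, drift, NLP injection strengths
(jump 0.35, sub-harmonic −6 dB, second voice at 1.78·f0 and −6 dB, chaos over
30% of the call) and the support caller effect are free parameters the source
study does not quantify; they were fixed once at values that make the
generator behave like a realistic scream corpus (identity recoverable at the
call level but far from perfectly; detectors operating with margin) and are
not tuned per test.

**What the generator does not emulate:** vocal-tract formants and
fundamental-frequency jitter/shimmer, reverberation, wind and background
fauna, overlapping screamers, microphone clipping, and perceptual
quality grading (quality is an input label, with a configurable fraction
marked poor).  Passing tests therefore demonstrate the *pipeline's*
correctness — segmentation rules, feature definitions, calibration of the
permutation machinery and of the mixed models — under a clean generative
model, not detector validity on noisy field recordings.

## Segmentation

The energy gate computes a moving-RMS envelope (5 ms), thresholds it at
−25 dB relative to the clip's peak envelope, merges active runs separated by
≤ 0.03 s into continuous vocal units, joins units closer than 0.3 s into one
scream utterance (spanning first-unit onset to last-unit offset), and drops
screams shorter than 0.05 s.  The gap band (0.03 s, 0.3 s) therefore
separates units of the *same* scream — the reading that keeps both printed
thresholds operative.  The detector parameters are configurable; when
annotations supply onsets/offsets the detector is skipped (annotation-
trusting mode, matching a manual-annotation workflow).  Events split on
≥ 30 s of quiet or a change of partners.

## Feature extraction

All spectral measures derive from a 512-sample Hann spectrogram at 90%
overlap (bin ≈ 86.13 Hz, hop ≈ 1.16 ms), linear power.  Choices the verbal
definitions leave open:

- **Transitions**: beginning/middle/end are the first, central and last 20%
  of frames; values are signed differences of window peak frequencies.
- **Quartiles**: first bin at which cumulative energy reaches 25/50/75% of
  the total (validated against a brute-force scan).
- **Entropy**: −Σ p log p / log N over the N bins of the normalized mean
  power spectrum, so the anchors (white noise 1, pure tone 0) hold for any
  FFT size.  Note the pure-tone anchor is exact only for a bin-centred tone:
  a 1 kHz tone at these settings falls 0.61 bins off-centre and the Hann
  mainlobe splits its power across two bins, bounding the measured entropy
  below by ≈ 0.135 (measured 0.157).  This is window leakage inherent to the
  pinned settings, not an estimator defect; with a bin-centred tone (e.g.
  1033.6 Hz) the measure returns < 0.01.
- **Modulation coefficients** (sd/mean and mean|Δ|/mean) are computed on a
  coarse dominant-frequency contour sampled at a fixed 20 time steps per call
  (Praat-style fixed-count stepping): frames within a step are averaged, the
  argmax refined by parabolic interpolation, octave flips folded, the result
  median smoothed.  Two failure modes motivate this: at the native frame
  rate the per-frame argmax jitters with broadband noise, turning the
  coefficients into noise meters (spurious severity effects); with
  fixed-*duration* steps mean|Δf| scales inversely with call length, turning
  the modulation coefficient into a duration proxy (spurious role effects).
- **Dominant-frequency band**: 100 Hz–Nyquist, excluding DC.
- Peak-frequency ties resolve to the lowest bin; degenerate inputs (zero
  energy, too few frames) yield NaN, recorded as missing, never dropped rows.

### NLP detectors

- **Jump**: the 20-step contour shows a sustained step — medians of
  adjacent 3-step windows differing by more than 22% of the call's median
  frequency, with an absolute floor of 2.5 bins so bin quantization on
  low-frequency calls cannot register as a jump.
- **Sub-harmonics / bi-phonation** work on the *order spectrum*: each
  5-frame block's spectrum is resampled onto a ratio axis f/f_dom(block)
  (parabolically refined), so drift and jumps leave harmonics at integer
  ratios.  Sub-harmonics: energy at ratio 0.5 within 10 dB of the dominant
  in ≥ 40% of blocks.  Bi-phonation: a non-harmonic spectral peak (ratio not
  within 4% of any ratio p/q with q ≤ 3, and off the half-integer comb by a
  margin that widens with bin-width/f0) above −9 dB at a *consistent* ratio
  in ≥ 30% of blocks — a real second voice keeps its ratio; noise bumps
  wander.  Bi-phonation on callers below ≈ 1.1 kHz is resolution-limited at
  a 512-sample FFT (the second voice merges with the harmonic mainlobes) and
  is missed symmetrically across conditions.
- **Chaos**: a sustained run (≥ 3 frames, ≥ 22% of frames) of high-entropy
  frames.  The threshold is adaptive by default — the call's 25th-percentile
  frame entropy plus 0.10 — because ordinary noisy calls sit near any fixed
  cut that full-depth noise segments must also cross; a fixed absolute
  threshold (`chaos_thresh`) remains available.

At the generator's default injection strengths the detectors achieve
per-form sensitivity ≥ 0.9 with ≤ 10% false positives on clean calls across
the study's noise range (verified in the test suite).  Strong injections of
one form can co-trigger another flag (chaos segments also register as
jumps); the bout-level `pct_nlp` counts screams with *any* form, so
cross-flagging does not distort it.

## Discriminant analysis

`CorrelationFilter` greedily removes features until all pairwise |r| ≤ 0.8
(dropping the member of the worst pair with the larger mean absolute
correlation).  `SymmetrizingScaler` picks, per feature, the transform among
identity/sqrt/log that minimizes |sample skewness| (offsetting non-positive
values for sqrt/log), then standardizes to mean 0, sd 1.  `FisherDiscriminant`
solves the generalized eigenproblem of between- vs within-class scatter and
classifies by nearest class centroid in discriminant space (ties to the
lowest label; a ridge is added to a singular within-class scatter and
flagged).

Balanced crossed subsets keep only test-factor levels present with at least
`min_per_cell` (default 2) samples in *every* control cell; per level × cell,
round(`train_fraction`·m) samples are drawn, where m is the minimum cell
count over the kept levels, capped so a holdout always remains.  The
achieved training share is reported rather than forced.  The unbalanced
crossed mode keeps all levels with enough samples overall and draws a
`train_fraction` share per occupied cell.

Permutations shuffle test-factor labels across calls *within control cells*,
preserving every cell's size so the crossed design stays applicable to each
permuted dataset; each permutation re-draws its own balanced subset (a flag
allows reusing one draw).  p-values use the add-one estimator, so p > 0
always.  Exchangeability note: with the observed rate averaged over many
subset draws but one draw per permutation, p-values are conservative
(super-uniform); the null-calibration test therefore runs with
`n_resamples=1`, where observed and permuted statistics are exchangeable and
the p-value is exactly calibrated.

## Mixed models

Gaussian responses: after the same symmetrizing transform and scaling, each
feature is fitted by REML with crossed random intercepts for caller and
event.  The fitter is a direct implementation — dense covariance
V = σ²(I + γ_c Z_cZ_c' + γ_e Z_eZ_e'), error variance profiled out,
Nelder-Mead over the two log variance ratios — validated against statsmodels'
MixedLM (variance-component formulation) in the tests; the direct form is
roughly fifty times faster at this problem size, which the replicated
acceptance simulations need.  Wald z intervals are reported (profile
likelihood out of scope).  R²: marginal = var(Xβ̂)/(var(Xβ̂)+Στ̂²+σ̂²);
conditional adds the random components to the numerator (logit models use
π²/3 as residual variance).

The support model is a binomial-logit GLMM with caller and 4-level context
random intercepts, fitted by a Laplace approximation: penalized IRLS finds
the joint mode of fixed and random effects given the variance parameters,
and Nelder-Mead maximizes the Laplace log-likelihood over the log standard
deviations; standard errors come from the fixed-effect block of the inverse
joint Hessian.  Validated by parameter-recovery simulation.

Exactly 36 p-values (12 responses × role, severity, interaction) are
BH-adjusted jointly; model failures are recorded in the ledger without
aborting the family.  Diagnostics flag |standardized conditional residual| >
3 and leave-one-caller-out shifts of any fixed effect beyond one standard
error; removals happen only under an explicit policy and are logged with
before/after estimates.

## Numerical and degenerate-input conventions

Times are seconds, half-open intervals [onset, offset); frequencies Hz
(peak frequency reported in kHz).  Audio other than 44.1 kHz is resampled on
read with a warning; 16/24/32-bit PCM normalize to [−1, 1].  Singular mixed
fits are flagged, not hidden; non-convergence raises with diagnostics.
Variance-parameter optimizations start at γ = 0.5 with log-scale bounds
[e⁻¹², e¹²].  Seeds fix entire datasets bit-for-bit, including WAV bytes.

## Validation scale

The replicated checks run at deliberately chosen sizes: permutation-null
calibration on 200 reduced studies (4 callers, 130 screams of 0.12 s, 200
permutations, single resample); effect recovery on 50 studies at full scale
(26 callers, 374 screams); support recovery on 100 annotation-only studies;
identity recovery on one full study at 100 resamples × 1000 permutations.
In the effect-recovery check, type-I error is assessed on effects that are
null *in the generator's ground truth*; the victim-duration manipulation
mathematically propagates to bout-level average scream duration and scream
rate, so those role contrasts are expected rejections, not false positives.

## Known limitations

- NLP detectors are algorithmic surrogates for what field studies code
  auditorily/visually; they are validated only against the synthetic
  generator's ground truth.
- Entropy is computed on the whole-call mean spectrum (frame-wise entropies
  appear only inside the chaos detector); the alternative averaging order
  would give systematically different values.
- The binomial GLMM's Laplace approximation is first-order; for very sparse
  support outcomes its variance components are shrunk relative to
  quadrature-based fitters (signs and magnitudes of fixed effects are
  recovered, which is what the analyses use).
- Caller attribution from audio is out of scope: who screamed is an
  annotation.  Overlapping simultaneous screamers are not modelled.
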