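# Methods

## The simulated task

The package models a three-alternative forced-choice (3AFC) word recognition
task delivered over headphones at home. On each trial one word from a
three-word set (25 sets, vowel-contrasted monosyllables) is presented; the
masker, when present, is a noise shaped to the long-term average spectrum
(LTAS) of the target corpus and is always diotic (M₀). Targets are diotic
(T₀) or inverted in one ear (Tπ). The binaural intelligibility level
difference (BILD) is the SRT improvement in M₀Tπ relative to M₀T₀.

Because playback happens on uncalibrated personal hardware, absolute levels
are referenced to the participant's "comfortable" setting (50% system
volume, roughly 60 dB SPL): masked levels are expressed in dB SNR re the
masker, quiet levels in dB re comfortable.

## Stimuli

`compute_ltas` concatenates the corpus, estimates the PSD by Welch's method
(segment length 4096), and averages it within base-2 one-third-octave bands
spanning 100 Hz–10 kHz. Band values are *density* levels re the corpus
mean-square-per-Hz, so unit-RMS white noise reads flat near 0 dB; empty
bands are floored (−300 dB) to keep magnitudes finite for line spectra.

`shape_noise` multiplies the FFT of white Gaussian noise by a
piecewise-constant per-band amplitude envelope (one-third-octave band edges
are contiguous, edge values held outside the range), zeroes DC, and
renormalizes to unit RMS. The band envelope is applied exactly, so
`compute_ltas(shape_noise(S)) ≈ S` to within spectral-estimation noise
(≲0.2 dB per band at 30 s, comfortably inside the 2-dB fidelity contract
over 200 Hz–8 kHz).

`assemble_trial` holds the masker at its reference level and scales the
target so that `20·log10(rms_t/rms_m)` equals the commanded SNR; adapting
the target with the masker fixed keeps masked audibility constant within a
track, the standard convention for speech-in-noise SRTs. In M₀Tπ the target
component is sample-wise negated in the right channel; in quiet the masker
amplitude is zero and the commanded level is dB re comfortable (unit-RMS
digital full scale).

The recorded corpus (female talker) is not distributable, so
`synthesize_corpus` provides a clearly labelled **synthetic** stand-in: 25×3
harmonic complexes (f0 jittered 150–300 Hz) with two formant resonances
rotated across the words of a set, plus an aspiration-like noise floor 18 dB
down. The floor and f0 diversity keep the corpus LTAS smooth, as for real
speech; the corpus emulates gross spectro-temporal shape only (no phonetic
content, no lexical confusability).

## Listener model

Each simulated participant has, per condition, a guess-corrected logistic
psychometric function

    p(correct | L) = γ + (1 − γ − λ) · Λ((L − μ)/s),   γ = 1/3.

A logistic rather than cumulative-normal link is used for its closed form;
at these spreads the two are indistinguishable. Defaults are spread
s = 2 dB and lapse λ = 0.02, typical human psychophysics values; the source
study measured humans and constrains neither, so both are free simulation
parameters, not estimates. The antiphasic midpoint is
`μ_m0tpi = μ_m0t0 − bild_true − hardware_anomaly_db`: the true BILD rigidly
translates the function, and the anomaly term models the observed outlier
household whose personal headphones inflated the antiphasic advantage by
7–10 dB while leaving M₀T₀ unremarkable. Word identity never affects
performance — word-set draws are presentation metadata.

The "true SRT" of a listener is defined as the level where
`p = 2^(−1/2) ≈ 0.707`, the asymptotic convergence point of a
two-down/one-up track, located by root-finding on the psychometric function.
Staircase recovery is therefore unbiased by construction in the steep-slope
limit.

## Staircase

Two-down/one-up: two consecutive correct responses move the level down one
step, any error moves it up one step. A reversal is logged at the pre-move
level when the intended direction flips (the initial descent has direction
"none", so the first up-step after a descent logs reversal 1); the intended
direction, not the bound-clamped position, drives the logic. A run finishes
at 8 reversals, and the SRT is the mean of the last 6. The study does not
report step sizes, start levels, or bounds; the package defaults to a
conventional Levitt-style schedule — 4-dB steps shrinking to 2 dB once two
reversals have been logged *before* the move, start at 0 dB SNR (masked) or
−10 dB re comfortable (quiet), bounds (−40, +20) dB SNR masked and
(−70, +10) dB re comfortable quiet, `max_trials = 150` as a guard against
non-converging responders. The quiet bounds are wider than the masked ones
because quiet thresholds near −45 dB re comfortable would otherwise clamp
and bias the track. Other schedules could shift mean SRTs by a fraction of
a dB.

A known, real property of this design: during the long descent to deep
quiet thresholds, occasional lapses insert reversal pairs above threshold
and trigger the early step-size reduction, producing a small positive bias
(≈0.3 dB at 25 dB of descent, ≈0.9 dB at 40 dB) in single quiet runs. The
masked tracks, starting ~10–17 dB above threshold, show no measurable bias.

## Protocol

Each session is seven runs: one quiet run first, then three blocks of two
masked runs, the within-block order of M₀T₀/M₀Tπ randomized by a fair coin.
Sessions occur on Days 1, 2, and 7. A day's per-condition SRT is the mean
of its (up to three) valid runs; the day's BILD is the M₀T₀ mean minus the
M₀Tπ mean; if every run of a condition fails, that aggregate is missing.
An optional drop mechanism (default off) marks runs invalid at random to
emulate upload loss, and a distraction flag can be injected as metadata
with no performance effect. Valid-run averaging is used throughout; the
source study does not state how erroneously repeated runs entered its day
means.

## Cohort generator

Listeners are drawn from an additive variance-component model. For a child:

    true_m0t0 = group_mean + age_slope·(age − age_mid) + N(0, σ_between)
    bild_true ~ N(mean_m0t0 − mean_m0tpi, σ_bild)
    true_quiet analogous with its own slope and σ

with ages uniform in the group range (so the age term is mean-zero at the
range midpoint) and adults without age trends. Group means are specified as
true SRTs at the 70.7% point and converted to psychometric midpoints via
the closed-form offset. Day-to-day variability enters as independent
zero-mean per-day, per-condition perturbations; there is no drift in group
means over sessions, consistent with the absence of practice effects in the
source data.

Calibration: the `paper_day1` preset stores the published Day-1 group means
(children/adults: M₀T₀ −8.9/−11.3 dB SNR, M₀Tπ −15.0/−17.1 dB SNR, quiet
−35.1/−42.1 dB re comfortable; n = 28/11). The published per-participant
BILD averages (5.8/6.1 dB) differ by 0.3 dB from the differences of the
published condition means (6.1/5.8 dB) — per-participant averaging with
unequal valid-run counts can do this — so the generator uses the
condition-mean difference as the BILD mean and treats the published BILD
figures as an emergent check within a 0.5-dB band.

The published study reports no dispersions for its group means, so the
variance components are package choices, documented and configurable:
masked between-subject SD 2.5 dB, BILD SD 2 dB, quiet between-subject SD
8 dB (quiet SRTs, measured in a single run, were visibly more variable,
ICC ≈ 0.5). Day-perturbation SDs are solved from the published test-retest
ICCs: for the short interval `σ_d = σ_b·sqrt((1−ICC₁₂)/ICC₁₂)`, and the
Day-7 SD from the Day-1/Day-7 ICC treating the pairwise correlation as
`σ_b²/sqrt((σ_b²+σ_d2²)(σ_b²+σ_d7²))`. The reliability presets used for
direct-matrix ICC recovery share one day SD across both columns
(exchangeable-days model), making the population consistency ICC equal the
published point estimate exactly. The child age slope (−0.55 dB/year) is a
generative choice producing a strong negative age–SRT correlation like the
one reported; it is not an estimate. Outlier listeners receive, with
configurable probability (0 in the calibrated preset), an antiphasic-only
advantage uniform in 7.1–9.6 dB.

Family clustering (siblings/parents sharing hardware), ambient-noise
covariates, and distraction effects on performance are not modeled.

## Statistical kernels

- **ICC**: single-measure two-way consistency coefficient ICC(C,1) from the
  ANOVA mean squares, `(MS_rows − MS_err)/(MS_rows + (k−1)·MS_err)`, with
  the exact F-based 95% CI (`F = MS_rows/MS_err` on (n−1), (n−1)(k−1) df).
  Rows with missing cells are listwise-deleted per day pair, and the
  estimate is reported as unavailable below 3 complete subjects. Labels:
  "good" 0.75–0.90, "excellent" > 0.90.
- **Pearson/Welch**: product-moment r with the t-transform one-tailed p;
  Welch's t with Satterthwaite df, one-tailed. Directions follow the
  developmental predictions: thresholds fall with child age, adults
  outperform children.
- **Prediction band**: OLS of SRT on age with the textbook
  `t·s·sqrt(1 + 1/n + (x₀−x̄)²/Sxx)` interval; remote child values outside
  the band fitted to laboratory-mode (simulated) child data are flagged
  with their side. Coverage is exact by construction and verified
  empirically at 95% ± 2%.
- **Audibility**: masked SRTs are converted to target levels re comfortable
  as `masker_ref + SRT` (default reference 0 dB: masker at the comfortable
  level — this conversion convention is the package's, since quiet and
  masked thresholds live on different scales); a listener×day dataset is
  flagged when the minimum masked target level is less than 6 dB above the
  quiet SRT (strictly-below-6 convention, so a margin of exactly 6 is not
  flagged).

ICC differences between day pairs are reported via CI overlap only; no
formal ICC-difference test is computed.

## What the simulations do and do not show

The generator reproduces the *group structure* of the published remote
data: means per group × condition, the BILD distribution, the ICC ladder
across retest intervals, rare anomalous-hardware listeners. It does not
reproduce individual human behavior: no lexical or phonetic confusions, no
attention or fatigue dynamics, no age dependence of psychometric slope, no
level dependence of binaural unmasking, and day effects are exchangeable
Gaussian perturbations rather than strategy or volume-setting changes.
Recovery of the calibrated values therefore validates the pipeline
(stimulus arithmetic, staircase logic, aggregation, estimators), not any
claim about listeners beyond the model's assumptions.

## Problem sizes and numerics

Recovery runs use 400 replicate cohorts (39 listeners × 7 staircase runs
each) for the group means and 500 replicate 39×2 matrices per reliability
preset — enough that Monte-Carlo error (≈0.16 dB SE for the smallest group)
is well inside the recovery bands. All randomness flows through explicit
`numpy.random.Generator` streams; fixed seeds give bit-identical trials,
runs, and sessions. Root-finding for the true SRT uses Brent's method at
1e−10 tolerance; the logistic is evaluated in its numerically safe form;
degenerate inputs (silent corpora, zero-variance matrices, collinear ages,
unreachable track targets) raise `ValueError` rather than returning
nonsense.
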