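# Methods

This note documents the models, parameter choices and numerical conventions
behind `speechpriors`, in the order the pipeline runs.

## Cochlear-position filterbank

Band edges are placed at equal basilar-membrane distance using the
Greenwood frequency–position function F(x) = A·(10^(a·x) − k) with the
standard human constants A = 165.4 Hz, a = 2.1 (position normalised to
[0, 1]), k = 0.88.  Between 100 and 5000 Hz this gives positions
0.0817–0.7109; n+1 edges are spaced uniformly on that interval and mapped
back to Hz.  Band *centres* are defined at the position midpoint of each
band (not the geometric mean of the edge frequencies), keeping the centre
definition on the same scale as the spacing principle; for these bands the
two definitions differ by under 1%.  Descriptions of such filterbanks
sometimes say "logarithmically spaced", which the Greenwood map approaches
at high frequencies; the equal-distance construction is the one
implemented, and the choice is recorded in the exported JSON manifest.

Bandpass filters are sixth-order Butterworth designs realised as
second-order sections; stability (all poles strictly inside the unit
circle) is asserted at design time.  On the designed digital filters at
22 050 Hz, every band's response at its own centre exceeds its response at
any other band's centre by ≥ 33 dB (8 and 16 bands), comfortably above the
20 dB selectivity margin the tests require.

## Sine vocoder

Per band: forward-only bandpass filtering, half-wave rectification, 30 Hz
fourth-order Butterworth low-pass (envelope), multiplication by a
zero-initial-phase sine carrier at the band centre, re-filtering with the
same bandpass, RMS restoration, and summation across bands.  Conventions
that were genuinely open and the choices made:

* **Filtering direction** — forward-only IIR, as a real-time vocoder would
  run; zero-phase filtering would change envelope latencies but none of the
  tested level or band-assignment properties.
* **Flip (spectral inversion)** — band *b*'s envelope drives the carrier
  and bandpass of band *n*+1−*b*, and the synthesized component is RMS-
  matched to the *source* band's analysis level, so inversion moves energy
  from high bands into low bands and vice versa: the long-term band
  spectrum of flipped speech is the mirror image of the original's.  The
  flip map is an involution.
* **RMS matching** — per band, ratio-based; a band whose analysis output is
  silent synthesizes silence.  Because rectification, filtering and
  ratio-matching are all degree-1 homogeneous, the whole vocoder is
  level-homogeneous (vocode(α·x) = α·vocode(x) in RMS).
* **SNR mixing** — the gain g = 10^(SNR/20)·RMS(masker)/RMS(target) is
  applied to the target, the masker is looped/truncated to target length,
  and the mixture is normalised to a common reference RMS (0.05) so that
  intelligible and control trials match in overall intensity.  Whether the
  original stimuli applied gain to target or masker and how they were
  re-levelled after mixing is not derivable from the construction; this
  convention is fixed here and recorded in the stimulus manifest.
* **Peak ceiling** — a final peak normalisation to |sample| ≤ 0.9 before
  WAV writing, applied identically to all stimuli, prevents clipping
  without disturbing relative levels.

The 'scratchy' attention target is flipped sine-vocoded material that is
subsequently noise-vocoded on the same filterbank (band envelopes ×
band-limited noise carriers), which raises spectral flatness relative to
sine-vocoded speech and gives the distinct timbre the naive-listening task
needs.

## Synthetic speech-like source

A seeded generator stands in for recorded sentences: a harmonic source at
~110 Hz with slow pitch drift (1/h harmonic roll-off up to 5 kHz), shaped
by three formant resonators whose frequencies random-walk inside typical
male-speech ranges (F1 300–800, F2 900–2200, F3 2300–3000 Hz; 50 ms frames
with filter-state continuity), amplitude-modulated at a per-seed syllabic
rate drawn from 3–5 Hz.  It reproduces the features the vocoder pipeline
depends on — harmonic structure, formant-like spectral envelope, slow
amplitude modulation, non-flat long-term spectrum — and nothing else: no
phonemes, lexicon or prosody, so nothing in this package can measure
*intelligibility*, only signal-level and decision-level properties.

## Experiment designs

All schedules are deterministic functions of (experiment, seed,
counterbalance index).  Pseudo-randomisation constraints (the
no-more-than-two-in-a-row rule of the naive-listening sequence; the
post-order-differs-from-pre rule) use seeded rejection sampling with a
bounded retry count (10 000), failing loudly rather than silently
violating a constraint.  Specifics:

* The one-shot design re-tests the identical 90-stimulus set after
  exposure; the retest order is a fresh seeded shuffle (whether the
  original procedure froze or re-randomised it is not stated anywhere the
  design could be read from).
* The 8-cycle session counts *unique* discrimination stimuli: 80 per
  acoustic condition, 160 per session, each heard once pre- and once
  post-exposure (320 presentation rows).  The sentence pool (default 320)
  guarantees no sentence recurs anywhere in a session; the intelligible and
  control sentence sets are disjoint by construction.
* The naive-listening sequence distributes 45 intelligible trials over six
  15-SVS blocks as a shuffled (8,8,8,7,7,7) split, plus 3 targets per
  block, with an 8-trial familiarization preamble (3 targets, 5 controls)
  flagged `phase=familiarization` and excluded from analysis tables.
* The memory list holds 18 hidden words (3 per block), 18 length-matched
  foils drawn from the same common-noun pool, 5 irregularly spelled
  reading-test words and 5 spelling-matched foils.
* The priming manipulation of the parallel one-shot experiment is carried
  only as a group label (primed/control); no computation depends on the
  priming audio itself.

## Signal detection

Equal-variance Gaussian SDT: d′ = z(H) − z(F), C = −(z(H)+z(F))/2,
β = exp(d′·C), which equals the likelihood ratio of the signal and noise
densities at the criterion location.  Rates of 0 and 1 are replaced by
0.5/n and (n−0.5)/n per class count *before* z-transforming; the correction
is applied per rate, not via the log-linear (add-½-to-everything)
alternative.  Outcomes are always computed per participant and only then
averaged — group-level pooled rates are never converted to a group d′.
The identity β = exp(d′·C) is asserted on every constructed outcome.

With 45 trials per class, the plug-in d′ estimator carries a small convex-
transform bias (≈ +0.04 at d′ = 1.5, criterion unbiased); this is a
property of the standard estimator, not of the implementation, and the
parameter-recovery check budgets for it.

## Observer model

One standard-normal latent trait (hallucination-proneness) drives all
individual differences.  Defaults (z-units unless noted):

| parameter | default | role |
|---|---|---|
| `mu_dprime_pre` | 1.5 | baseline discrimination, matching the one-shot task's difficulty regime |
| `exposure_gain` | 0.7 | mean post−pre d′ shift from template exposure |
| `noise_sd` | 0.3 | independent pre and post measurement noise around trait-determined means |
| `gamma_mod` | 0 (0.3 in `modulation`) | trait → exposure benefit |
| `gamma_naive` | 0 (1.0 in `naive`) | trait → spontaneous recognition, log-odds per trait SD |
| `beta_nart` | 0 (0.1 in `naive`) | reading score → recognition, log-odds per point |
| `mu_criterion`, `sd_criterion` | 0.2, 0.4 | conservative-leaning response bias spread |
| `alpha_recognize` | 0.5 | recognition intercept (≈ 62% recognisers at n = 134) |
| `q_encode` | 0.6 | P(Remember) for hidden words heard after the recognition point |
| `fa_lure` | 0.15 | foil endorsement, trait-independent |
| `r_base`, `k_rate`, `q_nart` | 0.05, 0.2, 0.4 | base Remember rate, Know rate, reading-test-word memory |

Because pre and post d′ carry *independent* noise around their
trait-determined means, corr(trait, Δd′) = γ_mod/√(γ_mod² + 2σ²) — the
closed form the coupling tests check (0.577 at γ_mod = σ = 0.3).

Questionnaire marginals are stipulated, not fitted to any human data: the
five-item auditory hallucination scale scores each item 1–4 by thresholding
trait + unit item noise at (−0.2, 1.0, 2.2), giving totals in 5–20 with
mean ≈ 9.3 and monotone E[score | trait]; the anomalous-perception and
delusion frequency totals are negative-binomial with log-link on the trait
(means 12 and 8, dispersion 2) to mimic the right skew of such scales; the
reading-test score is Normal(35, 5²) rounded and clipped, independent of
the trait by default with a `rho_nart` switch to induce the confounding
pattern where reading ability absorbs the recognition effect.

Recognition block uses a truncated geometric on 1–6 whose success
probability increases with the trait (logit −0.85 + 0.25·trait), putting
the mode early and the mean near 2.5 without claiming to fit any observed
block distribution.  All randomness flows from one root seed through named
`SeedSequence` spawns (cohort / discrimination / naive / memory), so each
stage is independently reproducible.

The trial-level response model is the same equal-variance SDT the analysis
assumes: P(yes | signal) = Φ(d′/2 − c), P(yes | noise) = Φ(−d′/2 − c).
`simulate_cohort_counts` draws the per-phase counts binomially — exactly
the distribution of tallied independent Bernoulli trials — and is the fast
path for replicated simulations; the trial-level and counts-level routes
are checked against each other in the tests.

## Statistics

* **Change tests** — paired t (Cohen's d = mean diff / SD diff) or
  Wilcoxon signed-rank (effect r = Z/√N, normal-approximation Z).
  `method="auto"` switches to Wilcoxon when Shapiro–Wilk rejects normality
  of the differences at α = 0.05 — an explicit stand-in for the informal
  "non-parametric data" judgement such analyses usually report.  All-zero
  differences under an explicit Wilcoxon request return p = 1; any other
  zero-variance difference vector is an error.
* **Partial correlation** — residualise both variables on the covariates
  (Pearson), or rank-transform everything first and then residualise
  (Spearman variant: ranks first, then residuals).  df = n − 2 − k.
* **One-sided Bayes factor** — the exact sampling density of r given ρ
  (hypergeometric form, evaluated in logs) integrated against a uniform
  prior on ρ ∈ (0, 1) (the width-1 stretched beta), `scipy.integrate.quad`
  at 1e−8 absolute tolerance.  For r = 0.02, n = 60 this yields
  BF₁₀ ≈ 0.18, matching what default-prior Bayesian correlation software
  prints for such data.
* **Repeated-measures ANOVA** — standard two-way fully-within
  decomposition; Greenhouse–Geisser ε per effect from the orthonormal
  contrast covariance, fractional corrected dfs reported (Huynh–Feldt
  behind a flag); the one-way collapse is cross-checked against pingouin to
  1e−9 in the tests.  A linear-trend contrast over blocks within the
  pre-exposure level is reported alongside (F = t² of the per-subject
  contrast scores).
* **Mixed 2×2 ANOVA** — delegated to `pingouin.mixed_anova`; a vanishing
  effect sum-of-squares with a zero error term is reported as F = 0, p = 1
  rather than NaN.
* **Logistic regression** — `statsmodels` ML fit; Wald z/p, OR = exp(b),
  95% Wald CIs; perfect separation is detected before fitting and reported
  as an error naming the offending predictor.
* **No multiple-testing correction** is applied anywhere; report objects
  carry the number of tests run so readers can adjust if they wish.
* Non-recognisers' recognition blocks are kept missing, never imputed.

## The four-way qualitative pattern

`qualitative_pattern` runs one full simulated study under the `naive`
scenario and checks: (a) significant pre→post d′ gain; (b) no significant
trait–Δd′ correlation; (c) recognition positively predicted by the
hallucination scale (OR > 1, p < 0.05); (d) memory specificity — the
hidden-word correlation significant and positive, with both control
correlations (lures, reading-test words) smaller in magnitude.  The
specificity clause is deliberately an *ordering* condition rather than a
demand that every control test be non-significant: with three genuinely
null significance checks at α = 0.05 the joint pass probability of a
"everything null must be non-significant" definition is capped at
0.95³ ≈ 0.86 regardless of how well the model works, which would make a
≥ 90% reproduction criterion unattainable by construction.  Under the
documented defaults the pattern holds in ≈ 96 of 100 seeded runs.

## Problem sizes and runtime choices

Monte-Carlo checks use: 2000 observers for parameter recovery; 2000
replicates at n = 60 for the type-I calibration of the modulation test
(via the counts-level fast path); 100 seeded end-to-end runs at n = 134
for the qualitative pattern; 300–400 replicates for ANOVA null
calibrations.  These sizes give binomial standard errors comfortably
inside the asserted bands while keeping the full suite under a minute.
Audio tests use 1–1.5 s synthetic sentences at 22 050 Hz.

## Known limitations

* The speech-like generator cannot support intelligibility or word-report
  measures; experiments that score keyword accuracy are represented only
  at the design/label level.
* The observer model is intentionally minimal: no learning within the
  pre-exposure phase (the block-trend machinery is exercised with
  constructed data), no attention lapses, no item effects.
* Questionnaire marginals are stipulated; passing tests show the analyses
  recover the couplings the generative model encodes, not that the model
  matches human score distributions.
* Greenwood constants are the standard human values; other species or maps
  are out of scope.
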