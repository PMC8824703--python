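# speechpriors

Tools for studying how top-down expectations shape the perception of
degraded speech, and how that relates to hallucination-proneness.  The
package rebuilds, end to end and with no external data, the machinery of a
four-experiment auditory-psychophysics design:

1. **Stimulus synthesis** — sine-vocoded speech (SVS): speech analysed
   through a bank of Butterworth bandpass filters spaced at equal
   basilar-membrane distance (Greenwood map) between 100 and 5000 Hz, each
   band's amplitude envelope (half-wave rectification + 30 Hz fourth-order
   low-pass) re-imposed on a tone carrier at the band centre.  Spectral
   inversion ("flipping", band *b* → band *n*+1−*b*) produces an
   unintelligible control with matched complexity; intelligible and control
   sentences are mixed at signal-to-noise ratios from −6 to +6 dB in 3 dB
   steps with 8 or 16 bands.  A seeded speech-like signal generator
   (harmonic source + time-varying formants + syllabic 3–5 Hz amplitude
   modulation) stands in for recorded sentences.
2. **Experiment designs** — seeded, reproducible trial schedules: a
   one-shot test–train–retest discrimination run (90 trials, 45/45), an
   8-cycle pre/exposure/post session over two acoustic conditions with a
   no-sentence-repetition constraint, and a naive-listening sequence
   (6 blocks × 15 SVS + 3 'scratchy' targets, max run length 2) with a
   46-word recognition-memory list.
3. **Signal detection** — per-participant yes/no outcomes summarised by
   equal-variance Gaussian SDT: d′ = z(H) − z(F), C = −(z(H)+z(F))/2,
   β = exp(d′·C), with extreme rates replaced by 0.5/n and (n−0.5)/n.
4. **Observer simulation** — a latent-trait generative cohort model
   (standard-normal hallucination-proneness trait driving questionnaire
   scores, discrimination, spontaneous recognition and hidden-word memory)
   with switchable `null`, `modulation` and `naive` scenarios.
5. **Statistics** — paired change tests (t / Wilcoxon), bivariate and
   partial correlations with a one-sided Bayes factor (uniform prior on
   ρ > 0, numerically integrated), 2×2 mixed ANOVA, 2×8 repeated-measures
   ANOVA with Greenhouse–Geisser-corrected degrees of freedom and a linear
   block-trend contrast, logistic regression of recognition group, and the
   memory-specificity correlation set.

The intended users are researchers in auditory psychophysics and
computational psychiatry who want a fully synthetic, inspectable testbed
for the *modulation* hypothesis (hallucination-proneness amplifies the
benefit of explicitly updated expectations) versus the *naive listening*
hypothesis (proneness predicts spontaneous decoding of degraded speech).

## Worked example

Simulate the naive-listening scenario at the study's sample size and run
the main analyses:

```python
import speechpriors as sp
from speechpriors.observers import sample_cohort, simulate_cohort_counts, _streams

params = sp.scenario_params("naive", n=134, seed=7)
cohort = sample_cohort(params)
counts = simulate_cohort_counts(cohort, 45, 45, _streams(params)["discrimination"])

gain = sp.paired_change_test(counts.d_prime_pre, counts.d_prime_post, method="t")
delta = counts.d_prime_post - counts.d_prime_pre
mod = sp.association(counts.lshs_a, delta, method="pearson", onesided_bayes=True)

cohort_df, mem_scores = sp.run_naive_cohort(params)
logit = sp.logistic_recognition(cohort_df.recognized.astype(int), cohort_df[["lshs_a"]])
mem = sp.memory_analysis(cohort_df, mem_scores)
```

Output:

```
d' pre  M(SD) = 1.58 (0.49)
d' post M(SD) = 2.37 (0.48)
exposure gain: t(133) = 13.12, p = 9.56e-26, d = 1.13
modulation: r(132) = -0.076, p = 0.385, BF10+ = 0.06
recognizers: 78/134
recognition ~ LSHS-A: z = 4.52, p = 0.000, OR = 1.44, CI = 1.23-1.68
memory: hidden rs = 0.41 (p = 0.000), lures rs = -0.09, reading-test words rs = -0.12
```

Reading this: template exposure produces a large, reliable discrimination
gain (d′ 1.58 → 2.37), but the size of that gain is unrelated to
hallucination-proneness (r ≈ −0.08, and the one-sided Bayes factor of 0.06
actively favours the null) — the modulation hypothesis fails.  Meanwhile
hallucination-proneness strongly predicts who spontaneously recognises the
hidden speech (odds ratio 1.44 per scale point) and how many hidden words
they later Remember (rs = 0.41), while lure endorsement and memory for
reading-test words show no such relation — the naive-listening signature.
That is exactly the dissociation the generative model encodes under the
`naive` scenario; the point of the pipeline is that every analysis recovers
it from simulated raw responses, not from the latent parameters.

A command-line layer exposes the same stages:

```bash
speechpriors synthesize --n-bands 8 --snr 6 --kind intelligible --seed 3 --out stimuli/
speechpriors design --experiment 3 --seed 1 --out exp3.csv
speechpriors simulate --scenario naive --n 134 --seed 2 --out sim/
speechpriors analyze --in sim/ --out results/
```

## Layout

```
src/speechpriors/
  filterbank.py   Greenwood map + Butterworth band definitions
  vocoder.py      envelopes, sine/noise vocoding, flipping, SNR mixing, WAV I/O
  designs.py      seeded trial schedules and the memory list
  sdt.py          d'/C/beta with extreme-rate correction
  observers.py    latent-trait cohort generator and response models
  stats.py        change tests, correlations, BF, ANOVAs, logistic, memory set
  cli.py          click entry points
docs/methods.md   model, parameter and design-choice documentation
```
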