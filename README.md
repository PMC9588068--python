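# pitchcomp

Analysis pipeline for **pitch-shifted auditory-feedback experiments**: when a
talker sustains a vowel while hearing their own voice with the fundamental
frequency (f_o) artificially transposed, they partially cancel the shift.
`pitchcomp` quantifies that compensation, decomposes each talker's
*spontaneous* f_o variability into slow (≤ 5 Hz) and fast (6–30 Hz)
fluctuation components, and tests — at the cohort level — whether talkers with
larger spontaneous slow variability compensate more, the behavioural
prediction of the motor-exploration hypothesis. It is written for speech /
sensorimotor researchers who have per-trial pitch tracks (delimited text or
Praat PitchTier files) and want a tested, reproducible version of the whole
chain, plus a synthetic-cohort generator so every stage can be validated by
parameter recovery without any recordings.

## The quantities it computes

For each participant and vowel:

- **Compensation ratio** — trials present one unshifted and one feedback-shifted
  vocalization (shifts 0, ±25, ±50, ±100 cents). After removing each
  participant's common trend (pointwise grand mean over trials), aligning each
  trial on its 50–150 ms baseline, and averaging the 0.8–1.2 s response
  plateau, the ratio is the **sign-inverted OLS slope** of plateau response on
  shift: 1 = full cancellation, 0 = no response. Participants with ratio ≤ 0
  are excluded from cohort correlations.
- **Variability indices** — SD of the f_o contour (cents, re 55 Hz) in the
  0.1–1.2 s window of unshifted first vocalizations, for the raw contour
  ("whole") and for its slow / fast components extracted with zero-phase
  2nd-order Butterworth filters (low-pass 5 Hz; band-pass 6–30 Hz).
- **Modulation spectrum** — RMS per band of a 28-band, half-octave-wide filter
  bank with quarter-octave-spaced centers `0.4·2^(k/4)` Hz (k = 0…27), on the
  200-Hz up-sampled contour.
- **Detection threshold and accuracy** — location and scale of a two-parameter
  cumulative-normal psychometric function `Φ((|shift| − θ)/s)` fitted by least
  squares to pooled yes/no listening-test responses.
- **Relative voice amplitude** — A-weighted, 40-ms Hann-window RMS envelope
  level in 0.1–1.2 s, centered on the cohort mean.

Cohort statistics: Pearson correlations with exact two-sided tests, paired
t-tests, one-way repeated-measures ANOVA with Tukey–Kramer post hoc
comparisons, stepwise (p-enter 0.05 / p-remove 0.10) multiple regression, and
**exact power** of the correlation test obtained by integrating the sampling
density of r (at n = 38, ρ = 0.37, α = 0.05 this gives 0.644, where the
Fisher-z approximation gives only 0.632).

## Worked example

```python
from pitchcomp import CohortConfig, simulate_cohort
from pitchcomp.workflow import build_cohort_table
from pitchcomp.stats import correlation_test

cohort = simulate_cohort(CohortConfig(n_subjects=40, coupling=0.4, seed=11))
table, _ = build_cohort_table(cohort, with_listening=False)
kept = table[table["ratio_a"] > 0]          # drop non-compensators
r, p, n = correlation_test(kept["var_slow"], kept["ratio_a"])
print(f"slow-variability vs ratio: r = {r:.3f}, p = {p:.4f}, n = {n}")
```

This simulates a 40-participant cohort whose compensation gain is coupled to
the slow-variability magnitude with target correlation 0.4, runs the full
pipeline (refinement → variability indices → compensation ratios), and
prints:

```
slow-variability vs ratio: r = 0.402, p = 0.0111, n = 39
```

i.e. the pipeline re-estimates the built-in coupling from raw simulated
trajectories; one subject happened to be excluded as a non-compensator.

The same pipeline runs from the shell on a dataset directory:

```bash
pitchcomp simulate --seed 1 --n-subjects 40 --vowels a --out data/
pitchcomp analyze  --in data/ --out results/
pitchcomp report   --in results/
```

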