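# Methods

This note documents the models, conventions and numerical choices behind
`pitchcomp`, in the order data flow through the pipeline.

## Trajectory representation

Pitch tracks are sampled on a fixed 10-ms grid (100 Hz) and carried in cents
relative to a base frequency of 55 Hz (`1200·log2(f/55)`); the base only
shifts contours by a constant, cancels in every SD, slope and correlation, and
is parameterized. Unvoiced or removed samples are explicit NaNs so that gap
filling, filtering and windowed statistics treat missingness uniformly.
External points (delimited text or Praat PitchTier, both "short" and "full"
layouts) are assigned to the nearest grid sample; how a variable-latency
voicing decision should map onto a fixed grid is genuinely underdetermined,
and nearest-sample assignment is the simplest convention that keeps a
round-trip exact.

Analysis windows are given in seconds after the vocal onset and converted to
half-open sample ranges `[round(t0/dt), round(t1/dt))`: baseline 50–150 ms,
plateau 800–1200 ms, variability/amplitude 100–1200 ms.

## Trajectory refinement

Autocorrelation pitch extraction leaves characteristic artifacts; refinement
applies five rules in a fixed order: (1) linear interpolation of missing runs
≤ 40 ms that are flanked by voiced samples; (2) removal of isolated voiced
islands ≤ 50 ms (both thresholds inclusive); (3) backward search from 200 ms
after the onset for consecutive-sample jumps > 100 cents — everything at and
before the latest such jump is detached and the onset redefined to the first
remaining voiced sample (harsh/aperiodic glottal pulsation at voice onset has
no perceivable pitch, so those samples cannot carry feedback information);
(4) the mirror rule searched forward from 300 ms before the offset; (5) in
the 210–1500 ms window, any > 100-cent jump is repaired by holding the
pre-jump value until the original contour returns within 100 cents of it.

Two details are our own resolutions of underdetermined cases. First, the
repair duration in rule 5 (how many samples a spike overwrites) is defined by
the return-within-threshold criterion above. Second, redefining the onset in
rule 3 moves the rule's own search window, so the backward scan iterates to a
fixpoint, and `refine_trajectory` repeats the whole five-step composition
until it is a no-op (all edits are monotone removals or idempotent repairs,
so this converges in practice within two passes). This makes refinement
idempotent, which is the property downstream code relies on. Trajectories
with < 0.5 s of voiced data after refinement are flagged unusable and
excluded.

## Compensation ratio

Per participant and vowel, second-vocalization trajectories of the
pitch-shift conditions are (a) detrended by subtracting the pointwise grand
mean over trials (computed over trials voiced at each sample, so unequal
lengths contribute where they exist), (b) baseline-aligned on their 50–150 ms
mean (the first 50 ms is excluded as unstable), and (c) summarized by the
mean of voiced samples in the 800–1200 ms plateau, requiring ≥ 50% voiced
coverage. The compensation ratio is the sign-inverted OLS slope of per-trial
plateau values on the shift (0, ±25, ±50, ±100 cents); fitting per-trial
points rather than condition means gives the same slope under a balanced
design while keeping the standard error interpretable. The 0-cent condition
participates in the regression. Detrending uses second vocalizations only;
whether first vocalizations should enter the grand mean is ambiguous, and
restricting to the trials being measured is the conservative choice (it is
configurable in code). Percent compensation at magnitude m pools
sign-inverted responses to +m with responses to −m and reports
`100·mean/m`; compensation opposing the shift is positive throughout.

## Variability decomposition

Before filtering, each contour is zero-centered on its voiced mean and
missing samples are set to zero; windowed SDs afterwards use voiced samples
only. Slow and fast components are extracted with zero-phase (forward plus
backward, `sosfiltfilt`) 2nd-order Butterworth filters: low-pass 5 Hz and
band-pass 6–30 Hz, at the native 100-Hz rate. Zero-phase filtering leaves
burst peaks within one sample of their input position. Note the filters are
shallow by construction: a 10-Hz sinusoid still leaks ~5–7% of its RMS
through the 5-Hz low-pass after the double pass — an inherent property of a
2nd-order filter one octave above cutoff, visible in the acceptance checks.

The modulation spectrum up-samples contours to 200 Hz (linear interpolation,
midpoints inserted and the final sample held, so 2 s stays 2 s) and measures
the RMS of 28 half-octave-wide, quarter-octave-spaced 2nd-order Butterworth
band-passes with centers `0.4·2^(k/4)` Hz, k = 0…27. A quarter-octave grid
from 0.4 Hz cannot land on 50 Hz exactly; we take every center ≤ 50 Hz (the
top band is ~43.1 Hz), and the band count is configurable.

Spontaneous variability uses first vocalizations only, excluding trials that
immediately follow an f_o-shifted trial (after-effect contamination); the
per-trial SDs are averaged per participant ("whole", "slow", "fast").

## Psychometric detection model

Listening-test responses are pooled over shift direction and vowel, giving
up to 8 repetitions per absolute shift (0, 25, 50, 100 cents); incomplete
designs record the actual n without padding. A two-parameter cumulative
normal `Φ((x − θ)/s)` is fitted by unweighted least squares on the rates
(a binomial-likelihood option exists but is off by default, matching the
rate-fitting description of the procedure this reimplements); the 0-cent row
anchors the lower asymptote, and there are no lapse/guess parameters. Fits
with all rates equal are non-identifiable (`converged=False`); step-like data
drive s toward zero and are flagged near-degenerate when s falls below a
tenth of the smallest level spacing.

## Cohort statistics

Pearson correlations use the exact two-sided t-test; the paired t-test and
the one-way repeated-measures ANOVA are standard, the latter computed from
raw sums of squares with the uncorrected univariate F (df (c−1), (c−1)(n−1))
and no sphericity correction — the degrees of freedom this analysis reports
require the uncorrected form, which is why the ANOVA is computed directly
rather than through a library default that may correct. Tukey–Kramer
comparisons use the ANOVA error term with the studentized-range distribution.
Stepwise regression is forward–backward selection by per-term p-value
(enter 0.05, remove 0.10, the common default of the tool family this mirrors)
over six candidates: slow and fast variability, detection threshold and
accuracy, relative amplitude, and gender; perfectly collinear predictors are
dropped greedily (earlier columns win) with a warning. Note that with six
null candidates the expected false-entry rate is ≈ 1 − 0.95⁶ ≈ 26%, so an
intercept-only model under a pure-noise response is the ~74% outcome, not a
near-certainty.

Power for the correlation test integrates the exact sampling density of r
under ρ (Hotelling's form, with the Gaussian hypergeometric term evaluated by
`scipy.special.hyp2f1`) over the rejection region |r| > r_crit. At n = 38,
ρ = 0.37, α = 0.05 this yields 0.6435; the Fisher-z approximation yields
0.632 and is kept as a cross-check mode. The exact density integrates to 1
to < 1e−6 and reduces to power = α at ρ = 0.

## Synthetic cohorts

The generator exists so every stage can be checked by parameter recovery.
A vocalization is `base + slow noise + fast noise + compensation term`
(2 s at 100 Hz). Noise components are white Gaussian sequences band-limited
by an FFT brick wall to 0.3–3 Hz (slow) and 8–16 Hz (fast) and scaled per
trial to the subject's magnitudes σ_slow, σ_fast. The bands are a deliberate
convention: they sit at the two modulation-spectrum peaks observed in real
sustained vowels (intonational drift at 2–3 Hz; physiological microtremor
near 10 Hz) *and* well inside the analysis filters' passbands. Shaping the
noise with the shallow analysis filters themselves would attenuate the
recovered slow SD by ~24% (the contour would be filtered twice), making the
generating magnitudes unrecoverable by construction; with the brick-wall
bands the indices recover σ within ~10% (the residual shortfall is window
truncation plus filter passband droop) and the quadrature relation
whole² ≈ slow² + fast² holds within 15%.

The compensation term opposes the shift with amplitude `gain·shift` and a
raised-cosine onset starting 0.15 s after the vocal onset and complete by
0.5 s. A smooth ramp that *saturates exactly* before the 0.8–1.2 s plateau is
essential: it makes the noise-free pipeline an identity on the gain (ratio
recovered to machine precision), which is the strongest possible correctness
check for the detrend → baseline → plateau → regression chain. An optional
reduced gain at |shift| = 100 (`gain100_factor`, default 0.85) reproduces the
saturation of percent compensation at large shifts.

Across a cohort, σ_slow ~ N(13.07, 3.72) truncated > 2 cents and
σ_fast ~ N(3.50, 1.2) truncated > 0.5 (the printed dispersion of the fast
index in the reference cohort is internally inconsistent with its own range;
1.2 places the range at ±2.4 SD). Gain is affine in σ_slow plus independent
Gaussian noise, with intercept, slope and residual variance solved so the
nominal gain mean (0.39), SD (0.21) and the σ_slow–gain correlation
(`coupling`, default 0.4) are hit; detection parameters θ ~ N(54.71, 16.69)
and s ~ N(14.13, 11.48) truncated positive; /u/ voice level sits 6.5 ± 2.8 dB
below /a/. The trial design contains all 13 conditions (6 pitch-shifted,
6 timbre-shifted — f_o-neutral — and 1 control) × 10 trials × 2 vowels in a
pseudo-random order; including the f_o-neutral timbre trials matters because
the follows-a-shifted-trial exclusion then retains ~77% of first
vocalizations, as in the emulated design. All randomness flows from one
cohort seed through per-subject and per-trial spawned seed sequences
(derived statelessly, so any single trial is reproducible in isolation), and
per-trial noise is batch-filtered, which is numerically identical to
per-trial filtering.

What the generator does *not* emulate: vibrato, voiced/unvoiced transitions
within a vowel, f_o declination nonlinearity, response-latency variability,
or any acoustic detail beyond a five-harmonic fixture tone for the amplitude
module. Passing recovery tests therefore validate the estimators under the
assumed statistical structure, not the structure itself.

## Problem sizes and runtime choices

The cohort-recovery experiment uses 100 cohorts of 40 subjects per arm
(coupled and null) and simulates /a/-vowel trials only, since the recovered
quantity — corr(slow variability, ratio) — is defined on the /a/ analysis;
this keeps the full experiment at a few minutes on one core. The recovered
mean correlation sits slightly below the generating coupling (~0.37–0.38 for
0.4): excluding estimated non-compensators truncates the low-gain tail, a
restriction-of-range attenuation inherent to the exclusion rule itself, with
a further ~1% from measurement noise in both indices.

## Known limitations

- The amplitude A-weighting uses the bilinear transform of the IEC 61672
  analog prototype; at 16 kHz its 1-kHz gain is within 0.1 dB but the
  response above ~6 kHz deviates from the analog curve (irrelevant for
  envelope-level statistics).
- The mid-vocalization repair rule holds a constant during a spike; a real
  octave error superimposed on a moving contour is repaired to the pre-jump
  level, not the (unknown) true contour.
- The unweighted least-squares psychometric fit ignores the binomial
  variance structure; with 8 repetitions per level the difference from a
  likelihood fit is well below the between-subject spread.
- `read_pitch_track` assumes a regular 10-ms extraction grid; pitch tracks
  produced with a different step are resampled by nearest-sample assignment
  without anti-aliasing.
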