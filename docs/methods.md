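# Methods

## Study design emulated by the generator

Each synthetic subject completes three sessions (standard, advanced, delayed
feedback) in a random order, four blocks per session. The told amount per
block is 300 s (temporal modality) or 750 m (spatial). Advanced/delayed
actual amounts are drawn without replacement from the fixed sets
{4.5, 4.0, 3.5, 3.0} min / {5.5, 6.0, 6.5, 7.0} min and
{675, 600, 525, 450} m / {825, 900, 975, 1050} m, so session totals are
always 15/20/25 min and 2.25/3/3.75 km. Treadmill speed is 70 % of the
subject's maximum running velocity (MRV ~ N(3.2, 0.25) m/s), which converts
spatial distances into durations.

**Prompt latency.** Temporal prompts carry a constant +2.0 s latency: every
measured block duration is the nominal amount plus 2 s. This models
operator/computer timing and gives the temporal standard condition a small,
constant, *nonzero* prediction error, while spatial distances trigger
exactly and the spatial standard error is exactly zero. This asymmetry is a
deliberate study condition: it is the only configuration under which a
hyperbolic error term (b/TE) is everywhere defined in the temporal modality
while hyperbolic SE forms must be excluded spatially — both properties the
candidate library depends on. Protocol-level (nominal) schedules are
unaffected.

**Physiology.** Per-subject latent parameters are stable across sessions:
baseline median frequencies (rectus ≈ 85 Hz, tibialis ≈ 110 Hz), an MDF
decline rate (~0.45 Hz per minute of running), mean-frequency and RMS
amplitude trends (~0.5 %/min decline and ~0.6 %/min rise — the two
ingredients of the Fatigue Index), and a saturating heart-rate response
(baseline ≈ 118 bpm, gain ≈ 28 bpm, time constant 6 min). Block-level
Gaussian noise (≈1 Hz on MDF, 1.5 bpm on HR) sits on top. These magnitudes
were chosen once as physiologically plausible for moderate treadmill running
and are not derived from any dataset.

**Ratings.** The per-block fatigue value is the chosen generating form
(default: the group-4 winner with a = 0.8, b = 0.5) evaluated at the *true
standardized* features, plus N(0, noise_sd) with noise_sd = 0.2. Each
subject's values are affinely mapped onto the 1–7 scale (range → [1, 7]),
and the map is recorded; by construction clipping never activates, so the
map inverts exactly. Ratings stay continuous by default (an optional
discretize mode rounds to integers), since the fitting pipeline normalizes
ratings anyway. Pleasure is baseline (≈4.5) plus noise with zero true
change. Order effects are not modelled — the design randomizes session order
precisely to remove them.

**Perceived totals.** perceived = actual + sign·(0.2·FI̅ + offset(condition)
+ noise), with sign +1 for advanced (over-estimation), −1 for delayed, and
condition offsets chosen *linear in the distortion condition code*
(standard = 1, advanced = 2, delayed = 3; base 30 s / 75 m, step 150 s /
375 m) so that the distortion regression — |perceived − actual| on FI̅ plus
the condition code — is correctly specified and its FI coefficient has known
truth 0.2. Note the identification is deliberately weak at these scales
(seconds vs. FI units; session-mean FI varies by only a few hundredths), so
the recovery check is a CI-coverage check, not a precision claim.

## Feature construction

Baseline is the first block of each session — the only within-session
reference present in every condition; MDF and HR enter as block-mean deltas
from it. The muscle-fatigue score is PC1 of the two muscles' MDF deltas
(columns standardized first; sign fixed so the score co-varies with the
column mean), z-scored across the modality's pooled rows. The alternative
metric is the z-scored composite Fatigue Index; switching metrics changes
only the `mf` column.

**Error standardization is scale-only** (divide by the pooled SD, no
centering), while MF and HR are fully z-scored. Centering cannot be used for
the error columns: with a symmetric design the pooled mean error is ~0, so
centering would annihilate the standard condition's constant error —
contradicting both the nonzero-constant temporal behavior and the
exactly-zero spatial behavior that the candidate library encodes, and making
hyperbolic error terms explode with alternating sign. The
`standardize_errors={scale,pooled,none}` switch exposes the alternatives.

Ratings are normalized within subject, SF̃ = (SF − avg)/std over the
subject's 12 blocks, absorbing scale usage. For ground-truth recovery
studies the recorded affine map is inverted instead (`sf_model` column):
the group-3–5 forms contain no intercept, so a per-subject recentered target
cannot return the literal generating coefficients; inverting the recorded
map tests the estimator against exactly what generated the data. Pipelines
on non-synthetic input use `sf_norm`.

## Fitting and model comparison

Every candidate form is linear in (a, b, c), so minimizing ERR_SF subject to
coefficients ≥ 1e-8 (the positivity constraint needs an epsilon to be
closed) is a convex problem. The default solver enumerates the 2^k active
sets of the bound, solves each candidate by pseudo-inverse least squares,
and keeps the best feasible one — exact, deterministic, and vectorized
across fit units, which is what makes scanning the full library
(344 temporal / 199 spatial specs) across all units cheap. The multi-start
bounded trust-region-reflective path (`method="multistart"`, uniform (0,1)
starts) reproduces the classic workflow and agrees with the exact path to
solver tolerance; it exists because multi-start least squares is the
standard guard against local minima, which this particular library does not
have.

**Fit unit** defaults to the subject (12 blocks across the three
conditions). Per-session units (n = 4) are supported but degenerate for
selection: with best-of-many form search, a 3-parameter spec can
near-interpolate 4 points and n·ln ERR_SF diverges, so the heart-rate group
would win spuriously. Pooled fitting is also available and is what the
parameter-recovery analyses use.

ERR_SF is floored at 1e-12 before logarithms (a perfect synthetic fit would
otherwise give −∞ criteria; floored values are flagged with a warning).
Within a group, forms are ranked by mean per-unit AIC, ties broken by mean
BIC, then smaller k, then form id. Specs whose design matrix cannot be built
(hyperbolic term at an exact zero) are skipped — the same rule that removes
1/SE spatially. Across groups, the winner minimizes mean AIC, and pairwise
**unpaired** permutation tests compare the per-unit AIC/BIC samples. Paired
differencing is wrong here: the parameter-count penalty shifts every unit's
difference by the same constant, so a paired test would flag any dropped
null term as significant regardless of fit.

## Resampling inference

Permutation tests enumerate the full arrangement space when it has at most
20,000 elements (label reassignments, or 2^n sign patterns for paired data)
and otherwise use seeded Monte-Carlo with p = (1 + #{|T*| ≥ |T|})/(n_perm+1);
the default statistic is the mean difference, with a t-statistic option.
Cohen's d uses the pooled SD for independent samples and the SD of
differences for paired designs. Bootstrap slope comparison resamples rows
within condition (default 5000 draws) and reports percentile CIs of pairwise
slope differences. The partial-regression residual comparison defaults to a
pooled covariate fit (one OLS over all rows, residuals split by condition):
per-condition fits include per-condition intercepts that absorb exactly the
mean shifts the comparison is meant to detect; `fit="per_group"` retains the
per-condition variant. The nested regression comparison converts per-unit
residual sums of squares into the same AIC/BIC parameterization as the model
selection. No multiple-testing correction is applied by default; raw
two-sided p-values are reported throughout. Condition enters regressions as
a numeric ordinal code — (advanced, standard, delayed) = (1, 2, 3) for the
main analyses, (standard, advanced, delayed) = (1, 2, 3) for the distortion
regression.

## Signal processing

Zero-phase filtering throughout (filtfilt/sosfiltfilt): 50 Hz IIR notch
(Q = 20, chosen so a pure mains tone loses ≥ 20 dB even on short windows
while tones 5 Hz away change < 5 %), fourth-order Butterworth band-pass
20–500 Hz (legal at fs = 1111 Hz; Nyquist 555.5 Hz). Heel strikes are upward
crossings of the midpoint between the 5th/95th percentiles, with a 0.25 s
refractory period and a noise-floor guard (the robust range must exceed six
robust SDs, so noise-only traces yield zero events). Per-step spectra use a
Hann-tapered periodogram of the detrended segment — Welch averaging would
blur the ~0.35 s per-step resolution — with median frequency interpolated
linearly within the crossing bin. Steps shorter than 64 samples, or with
duration/RMS outside Tukey fences (k = 1.5, with an absolute ulp-tolerance
so exact ties at a zero-IQR fence are kept), are dropped as irregular
movements. Heart-rate samples outside [40, 200] bpm (bounds inclusive — the
bounds define the normal range) are removed before low-pass smoothing; the
requested 10 Hz cutoff is clamped to 0.45·fs when the sampling rate cannot
support it (at 10 Hz sampling the effective cutoff is 4.5 Hz, logged).
Blocks are split into 10 contiguous near-equal parts (remainder on the
leading parts) whose means feed the block aggregates.

The EMG synthesizer writes each inter-step segment in the frequency domain
as complex Gaussian noise on a flat 40 Hz band centred on the step's target
median frequency — sufficient for a prescribed MDF trajectory, and
deliberately not a physiological motor-unit model. At running cadence
(2.8 strikes/s) a single step supports MDF estimation to only ~5 Hz; the
estimator-fidelity checks therefore use 1 s steps, where per-step agreement
with the generating schedule reaches rank correlation > 0.9.

## What the synthetic tests do and do not show

Passing tests demonstrate that every stage recovers the truth *its own
generator injected*: the pipeline is internally consistent, correctly coded,
and calibrated (type-I error, CI coverage). They do not show that real
running data obey the group-4 form, that real EMG spectra behave like
band-limited Gaussian noise, or that real rating scales are affine —
generator realism is limited to the trends and magnitudes listed above.
Reproducing the human-study statistics would require the original dataset
and is out of scope.

## Problem sizes used by tests and the acceptance script

Cohorts of 30 subjects (27 spatial) — the study's sample sizes; 20 seeded
cohorts per modality for selection recovery and 10–20 for parameter
recovery (multistart with 10 restarts); 100 seeds for the band-limited noise
oracle; 1000 replications (per tail shape) for permutation type-I
calibration; 200 replications for bootstrap coverage. These sizes keep each
analysis in the seconds-to-minutes range while leaving the binomial noise on
the reported rates well inside the tolerances asserted.
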