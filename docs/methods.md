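# Methods

This note records the models, conventions and deliberate design choices
behind the package, in the order the pipeline runs.

## Acti-count preprocessing

Research-grade wrist actigraphs derive activity counts from raw
acceleration through a proprietary but broadly standard chain. The
package's open reimplementation is:

1. **Gravity removal before combination.** Gravity and postural drift are
   estimated per axis by a centred 10-s moving mean (replicated-edge
   padding) and subtracted; the three residuals are combined by the
   per-sample Euclidean norm. Combining first and filtering the
   nonnegative magnitude afterwards would fold the rectification harmonics
   into the passband, so the axis-wise mean removal happens first and only
   the combined magnitude is band-passed.
2. **Band-pass 0.5–3 Hz.** 4th-order Butterworth, applied
   forward–backward (`sosfiltfilt`): zero phase, squared magnitude
   response. Passband gain at 1.5 Hz is within ±1 dB; attenuation at
   0.05 Hz and 10 Hz exceeds 20 dB. Edge minutes are retained, not
   trimmed; the filter's edge transient is confined to a few seconds.
3. **Threshold–integrate–average.** The filtered signal is rectified;
   samples at or below a threshold (default 0.01 g) are zeroed; surviving
   samples are summed within consecutive 2-s segments; the minute's
   acti-count is the mean of its thirty 2-s sums. Device conventions
   differ on whether 1-s epochs or 2-s integrals are averaged; the
   2-s-sum / minute-mean reading is the default and both the threshold
   and segment length are parameters, since no calibration for the
   original device is public. Activity units are therefore arbitrary;
   only within-pipeline comparisons are meaningful.

Consequences worth knowing: counts are nonnegative for any input;
with threshold 0 the chain is exactly homogeneous (scaling the movement
amplitude by k scales counts by k); a perturbation confined to one minute
reaches only its immediate neighbours (IIR leakage beyond that is below
the threshold floor).

Missing data are never imputed: gaps must appear as explicit empty-count
rows in the epoch CSV, and exclusion decisions happen downstream.

## Nonparametric RAR indicators

The indicators operate on hourly averages `X_i` over whole calendar days
(local midnight boundaries, naive local clock time; M10/L5 are clock-time
quantities).

* **IS** — variance of the 24-point daily template over total variance,
  scaled by `N/p`; 1.0 for a perfectly repeating (nonconstant) day, and
  approximately `1/D` for white noise over `D` days (the exact finite-N
  expectation for 7 days of iid noise is ≈ 0.137).
* **IV** — normalised mean-squared first difference; ≈ 2 for white noise,
  `2(1 − cos(2π/24)) ≈ 0.068` for an hourly-sampled 24-h sinusoid, and 4
  in the strictly alternating limit. First differences are taken only
  between hours adjacent in real time: pairs spanning an excluded day are
  skipped.
* A constant series has no rhythm to normalise by; both IS and IV raise
  an explicit "undefined: constant series" error rather than returning a
  number.
* **M10/L5** — moving-window search at 1-minute resolution (600- and
  300-minute windows), constrained within each calendar day. A circular
  (midnight-wrapping) search is available behind `wrap=True` for
  night-spanning sleep; an hourly-resolution search behind
  `resolution="hour"`. Ties break to the earliest clock time, with a
  small absolute tolerance so that floating-point jitter in the running
  sums cannot break an exact tie.
* **Composites** — M10 and L5 are averaged over retained days and RA is
  computed from the composites (not as the mean of daily RAs): applied to
  a published sample recording's composite pair this convention
  reproduces the printed RA exactly.

**Missing-data policy:** an hour with fewer than 45 valid minutes is
invalid; a day containing any invalid hour is excluded from *all* metrics
(IS, IV and the window search alike), and exclusions are reported and
logged. Both thresholds are configurable. Fewer than 7 retained days
raises "insufficient days" unless explicitly forced (logged).

**Invariances:** IS, IV and RA are exactly invariant to positive scaling;
M10/L5 scale linearly. Circularly shifting every day by the same offset
leaves IS and (with `wrap=True`) M10/L5/RA unchanged and translates the
onsets; IV is shift-invariant only up to O(1/N) day-boundary edge
effects, because the first-difference sum is not circular.

## Synthetic data

The generator emulates the statistical features the indicators are
designed to detect, at inpatient-rehabilitation activity levels:

* **Envelope:** `mesor + amplitude · max(0, cos(2π(t − acrophase)/24))`
  per day — a rectified cosine, so nights sit on a true nonnegative floor
  (the mesor) rather than a negative half-wave.
* **Day-to-day jitter:** the acrophase and amplitude are redrawn each day
  (normal, SDs `phase_jitter_sd`, `amp_jitter_sd`) — this is what erodes
  IS.
* **Fragmentation:** a two-state active/rest Markov chain at 1-minute
  resolution (symmetric switch probability `frag_rate`, started active)
  multiplies the *rhythmic component only*; the mesor stays an additive
  floor. Because IS and IV are invariant to an additive constant, this
  decouples the nocturnal floor (which drives L5 and RA) from the
  stability/fragmentation indicators — deliberately, so a floor contrast
  between groups moves L5/RA without dragging IS/IV along. Mean IV rises
  with `frag_rate` in the sparse-switching regime (roughly up to ~0.05
  per minute) and falls again at high rates, where hourly averaging
  washes the fast switching out.
* **Noise:** additive within-minute Gaussian noise, clipped at zero.
* **Raw accelerometry:** the same envelope×fragmentation process drives
  2-s movement bursts (sinusoids at random frequencies inside 0.8–2.5 Hz,
  random 3-D direction, amplitude proportional to the activity level) on
  top of a (0, 0, 1 g) gravity vector plus white sensor noise. An
  optional `minutes` cap truncates the emitted recording for desk-scale
  use.

**Shipped cohort ("paperlike").** Two groups of 25, seven days each. The
stroke-like group has a raised nocturnal floor (mesor ~4.3 vs ~1.8
units/min, anchored to the published L5 group medians of the poststroke
inpatient study this design emulates) and a slightly lower daytime
amplitude (83 vs 90) chosen so the *expected* composite M10 matches
between groups; all other parameter distributions are shared. In
expectation the groups therefore differ in L5 and RA but not in M10, IS
or IV — the published significance pattern. Clinical scores are linked
linearly to the generator's own ground truth (Barthel Index increasing
in daytime level and day-to-day stability, 4AT decreasing in envelope
RA), with noise, rounding and clipping to the instruments' ranges
([0, 100] and [0, 12]); the 4AT is attached to the stroke-like group
only, mirroring its clinical administration. Coefficients produce
moderate rank correlations (|ρ| ~ 0.3–0.7); they are plausibility
choices, not estimates.

Randomness uses one root seed with per-participant child streams
(`SeedSequence.spawn`), so cohorts are byte-reproducible and participants
independent.

What the simulator does **not** model: sleep architecture, naps as
structured events, medication or apnea effects, nonwear, device
miscalibration, weekday/weekend structure. Passing tests demonstrate the
pipeline's correctness and sensitivity under this generative model, not
clinical validity on real recordings.

## Statistics

All comparisons are two-sided and nonparametric regardless of the
Shapiro–Wilk screen, which only annotates the report (inpatient RAR
variables are rarely normal, and mixing test families by per-variable
normality outcomes makes results harder to compare across studies).

* Mann–Whitney U: exact two-sided p by full enumeration of assignments
  when `n_a + n_b ≤ 12` and the pooled sample is tie-free; otherwise the
  normal approximation with midrank tie correction and continuity
  correction. Reported statistic is `min(U_a, U_b)`.
* Spearman ρ: Pearson correlation of midranks; exact two-sided
  permutation p for `n ≤ 7`, t approximation otherwise. Pairs with a
  missing score are dropped and counted.
* Categorical: chi-square without continuity correction, switching to the
  Fisher exact test (point-probability two-sided rule) for 2×2 tables
  with any expected cell below 5; the choice is logged.
* Quartiles by linear interpolation between order statistics (conventions
  differ across software; this one is stated rather than assumed).
* No multiplicity adjustment by default — the report says so explicitly —
  with Holm available per test family via `adjust="holm"`.

## Pipeline

A single validated config (YAML or constructor; unknown keys rejected)
drives `simulate → preprocess → metrics → compare`. Artifacts are plain
CSV plus a provenance sidecar carrying the resolved config, seed, package
version and a config hash — and no wall-clock timestamps, so a rerun with
the same config and seed is byte-identical. Every participant exclusion
(invalid days, missing metrics rows) is logged with a reason; stage
errors name the stage and participant.

## Problem sizes in the test suite

The behavioural suites run at deliberately modest sizes: closed-form
IS/IV limits use 7×24 to 70×24 hourly grids (1000 and 200 replicates),
generator monotonicity checks use 200 replicate weeks per parameter
value, the contrast-recovery check uses 100 replicate 50-participant
cohorts and the type-I calibration 1000 null cohorts (rejection rate
pooled over the five indicators). These sizes put Monte-Carlo error
comfortably inside the asserted bands while keeping the full suite in the
low minutes on one CPU.

## Known limitations

* Activity units are uncalibrated; absolute M10/L5 levels are not
  comparable across devices.
* The calendar-day window constraint can clip a genuinely night-spanning
  L5; use `wrap=True` when the population sleeps across midnight.
* IV's non-circular first difference makes it only approximately
  invariant to within-day time shifts and slightly sensitive to excluded
  days (handled by skipping boundary pairs).
* Timestamps are naive local time; daylight-saving transitions are not
  modelled (a 23/25-hour civil day would be rejected as a partial day).
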