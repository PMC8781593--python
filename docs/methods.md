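# Methods note

This note records the analytical definitions, the statistical models,
and the design of the synthetic-cohort generator, including every
default parameter and its rationale.

## 1. Data model

Two input tables, both CSV:

**covariates.csv** — one row per child: `child_id`, `birth_date`
(ISO 8601), `sex` (male/female), `birth_mode` (vaginal/c_section),
`birth_term` (full_term/early_term), `older_siblings` (0/1/2+),
`breastfeeding` (none/1-3 months/4-6 months/7-13 months, exclusive
duration), `daycare_entry` (0-12 months/13-26 months/none_by_24mo),
`pets` (yes/no), `birth_weight_g`.

**diary.csv** — one row per child per *observed* day: `child_id`,
`date`, ten symptom columns (`fever`, `wheezing`, `wet_cough`,
`dry_cough`, `chills`, `sore_throat`, `runny_nose`,
`high_need_for_sleep`, `loss_of_appetite`, `attachment`) coded
0 = absent, 1–3 = present with increasing severity, and two diagnosis
flags (`dx_pneumonia`, `dx_otitis_media`, 0/1). A day of life with no
row is a missing diary day. Days outside the observation window are
dropped with a log message. Validation rejects unknown children,
duplicate child-days, out-of-vocabulary covariate levels and symptom
codes outside 0–3.

The observation window is days of life 0–729 inclusive (730 days,
"first two years"). Children with completeness `observed_days / 730 ≥
0.98` are included; the threshold is configurable.

## 2. Day classification and episode segmentation

Symptoms split into class A (specific: fever, wheezing, wet cough, and
either diagnosis flag) and class B (non-specific: the remaining seven).
Severity codes 1–3 all count simply as "present"; severity never
substitutes for symptom multiplicity. Each observed day is classified
as `A_DAY` (≥1 A-symptom), `B_PAIR` (≥2 *distinct* B-symptoms and no
A-symptom), `SINGLE_B`, or `FREE`; unobserved days are `MISSING`.

The segmenter is a single left-to-right state machine per child:

- **Open** an episode on the first `A_DAY` or `B_PAIR` day (the start
  rule). A `SINGLE_B` day outside an episode never opens one; it is
  recorded in `orphan_days.csv`.
- **Inside** an episode, any symptomatic day (including `SINGLE_B`)
  resets the symptom-free counter.
- **Close** when the counter reaches 3 symptom-free days; the episode
  end is the last symptomatic day and `duration = end − start + 1`.
- **Missing days**: under `free` (default) a missing day increments the
  symptom-free counter, so an episode can end through a gap; under
  `pause` missing days neither reset nor advance the counter.
- **Censoring**: an episode still open at the window's last day — i.e.
  fewer than 3 symptom-free days could be observed after its last
  symptomatic day — is kept with `censored = True`.

Each episode records its trigger (`A_symptom` vs `B_pair`), start/end
day of life, duration, censoring flag, and the number of symptomatic
days it contains. Every symptomatic day belongs to at most one episode
or the orphan list — never both, never two episodes. The test suite
checks the state machine against an independent brute-force
re-implementation (quadratic jump-and-rescan) on randomised diaries
under both missing-day rules.

## 3. Strata and summaries

Episodes are assigned to age strata by **start day**: six-month strata
0–6 mo = days 0–182, 7–12 mo = 183–365, 13–18 mo = 366–547,
19–24 mo = 548–729; yearly strata split at day 365/366. Per-child
counts over six-month strata and over years both sum exactly to the
two-year count.

Symptom-day burden counts every observed day on which a symptom or
diagnosis flag is present, episode or not; wet and dry cough pool into
one "cough" group. Distribution summaries report min, Q1, median, mean,
Q3, max. All quantiles throughout use the linear-interpolation
convention (numpy/pandas default). Cumulative per-child distribution
curves are empirical CDFs.

In-episode prevalence on a day (of life, or calendar month) is the
number of children observed and inside an episode divided by the number
observed; monthly prevalence aggregates child-days by calendar month of
the actual diary date.

## 4. Statistical models

**Poisson regression.** Two-year episode counts are modelled with a
log-link Poisson GLM (statsmodels), covariates entered with treatment
coding. Reference levels: breastfeeding 4-6 months, daycare
none_by_24mo, birth mode vaginal, term full_term, sex male, siblings 0.
Crude RRs refit one covariate at a time on its own complete cases; the
adjusted model contains all six covariates (10 non-reference indicator
columns). Confidence intervals are Wald on the log scale,
`exp(β ± 1.96·SE)`. By default there is no exposure offset — every
included child contributes ≥98% of the same 730-day window, so counts
are directly comparable; `offset_days` optionally adds
`log(observed days)`. Complete-case analysis; unseen covariate levels
raise, single-level covariates are dropped with a warning; integer
counts are enforced and all-zero cells warned about.

**Mean differences.** Descriptive stratum comparisons use Welch's
unequal-variance *t* (scipy `ttest_ind(equal_var=False)`), reporting
the difference in means with its 95% CI. Descriptive reference levels
follow cohort-table convention (e.g. sex reference female) and may
differ from the regression references.

## 5. Synthetic-cohort generator

A discrete-time renewal process over each child's 730 days. On each
at-risk day the onset probability is

`p_i(d) = c_i · a(age_d) · s(month_d)`

- **Age profile** `a`: piecewise-linear through knots (day,
  multiplier) = (0, 0.05), (91, 0.45), (182, 1.05), (456, 1.17),
  (729, 1.05), then normalised to mean 1 over the window. The shape
  encodes maternal-antibody protection in the first weeks, a steep rise
  over the first months, and a mild late-second-year decline; the knots
  were set so the stratum-wise episode means and the median age at
  first episode land in the ranges typical of intensively followed
  birth cohorts.
- **Seasonality** `s`: sinusoid with amplitude 0.3 peaking in January
  (or an explicit per-month table), normalised to mean 1.
- **Per-child rate** `c_i`: covariate effects are specified as rate
  ratios on the *expected count* scale. Because time inside an episode
  (plus a refractory gap) is not at risk, a hazard-scale effect would
  attenuate on the count scale. The generator inverts the occupancy
  feedback per child by solving `c = h·(T − c·D̄)` for the expected
  count `c`, with `T` = at-risk window length and `D̄` = mean episode
  duration + 3; fitted Poisson RRs therefore recover the generating RRs
  without attenuation. The baseline is calibrated empirically so the
  cohort mean equals `mean_episodes`.

**Episode emission.** Duration is lognormal with mean 11 and SD 5.8
days (moment-matched parameters), truncated at ≥1 and rounded. Day 1 is
guaranteed to satisfy the start rule: with probability `p_a_trigger`
(0.6) an A-symptom trigger, otherwise two distinct B-symptoms (with
A-symptoms suppressed that day). Subsequent days draw each symptom
independently (probabilities below); any all-free draw inside an
episode is patched to show ≥1 symptom. Severity is 1/2/3 with
probability 0.6/0.3/0.1. Diagnosis flags occur only on A-triggered
first days (probability 0.01 each). After each episode at least 3
symptom-free days are enforced before the next onset, and orphan
single-B days (rate 0.01/day) are excluded from `[start, end+3]` of any
episode. These guarantees make segmentation of a complete diary
*exactly* reproduce the latent truth table, which the tests verify.

**Symptom probabilities per episode day** (chosen to reproduce
realistic per-symptom day burdens given ~150 episode days/child):
runny/blocked nose 0.83, wet cough 0.30, dry cough 0.28, increased
attachment 0.27, increased need to sleep 0.155, loss of appetite 0.15,
fever 0.09, wheezing 0.075, sore throat 0.021, chills 0.003.

**Covariates** are drawn independently per child: male 0.48; older
siblings 0/1/2+ = 0.682/0.255/0.063; breastfeeding
none/1-3/4-6/7-13 months = 0.056/0.094/0.618/0.232; daycare entry
0-12/13-26/none = 0.34/0.504/0.156; c-section 0.23; early term 0.076;
pets 0.278; birth weight N(3400, 488²) g. Default rate ratios: daycare
0-12 mo 1.27, 13-26 mo 1.27; siblings 1 = 1.08, 2+ = 1.17;
breastfeeding none 0.90, 1-3 mo 0.78, 7-13 mo 1.00; c-section 0.99;
early term 1.10; female 1.01. Birth dates are uniform over the
configured birth year (default 2015).

**Missingness** removes each diary row independently with probability
0.01 (default; capped at 0.02 so the 0.98-completeness filter retains
most children).

All defaults are fixed study conditions: they were set from the design
targets above before the evaluation suite was run and are not adjusted
to test outcomes.

### Scope and limitations

The generator reproduces: realistic symptomatic-day fraction and
per-symptom burdens, episode frequency with age and winter seasonality,
duration distribution, exact start/stop semantics, orphan days,
censoring at the window edge, covariate effects recoverable by Poisson
regression. It does **not** emulate: between-child frailty beyond the
covariates, so episode-count dispersion is sub-Poisson (SD across
children ≈3 rather than the ≈5 seen in real cohorts); within-family or
outbreak correlation; symptom autocorrelation within an episode
(symptom draws are day-independent given episode membership);
informative missingness (drop-out is uniform); or care-seeking
behaviour beyond the two rare diagnosis flags.

## 6. Numerical and reproducibility choices

- All randomness flows from one root seed through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.
- Pipeline CSVs are written with `float_format="%.6g"`;
  `manifest.json` records the config hash and SHA-256 of every output,
  and reruns of the same config are byte-identical.
- Standard problem sizes: 288 children for default-condition analyses
  (≈206k child-days, runs in seconds), 2000 children for
  rate-ratio recovery checks (tightens the Monte-Carlo error on RRs to
  a few percent while keeping runtime under a minute).
- 95% intervals use the 1.96 normal quantile (Wald) for RRs and
  scipy's exact Welch–Satterthwaite interval for mean differences.
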