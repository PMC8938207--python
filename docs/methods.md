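# Methods

## Data model and monitoring protocol

Each patient contributes a clinical record (age in months, sex, etiology,
intra-operative opening pressure in mmHg, outcomes at 1/3/6 months) and an
hourly ICP series indexed from the start of monitoring. In the protocol the
pipeline assumes, monitoring begins four hours after skin closure; that
offset is metadata and does not enter the indexing. Day windows are
half-open and zero-based: hours 0–23 are postoperative day 1, 24–47 day 2,
48–71 day 3. Readings beyond hour 71 lie past the fixed three-day analysis
horizon and are ignored with a logged warning rather than rejected.

Pressures must be finite, non-negative, and below 100 mmHg; a value outside
that window is a validation error, never clipped, because the most likely
cause is a unit mistake (cmH2O instead of mmHg).

## Daily average values

`DAV_d` is the arithmetic mean of day *d*'s hourly pressures. A day's DAV
exists only when at least `min_readings_per_day` readings were captured.
The default is 24 — a day counts only when complete — because the analysis
averages "the 24 values of each day" and excludes interrupted monitoring
wholesale; how partially recorded days should be treated is genuinely open,
so the threshold is exposed as configuration down to 1. A patient is
*analyzable* when all three DAVs exist; incomplete patients carry no trend
calls and drop out of every downstream table.

## Trend classification

At margin δ (mmHg, > 0) a trajectory is **progressive increase** iff

* `DAV1 < DAV2 < DAV3` (strictly monotone), and
* `DAV3 − DAV1 > δ` (strict).

Everything else is **stable**. Three deliberate choices:

* *Ties break toward stable.* Stable is defined as the complement of
  progressive increase, so any ambiguity defaults there.
* *Both inequalities are strict.* A net rise of exactly δ is stable.
* *No rounding before comparison.* Rounding conventions vary; exact
  comparison on the computed DAVs is reproducible.

Whether the middle day must participate in the rise (monotone reading) or
only the net day-1→day-3 difference matters cannot be decided from
published counts — both readings produce the same nested tables — so the
monotonicity clause is a switch (`require_monotone`, CLI
`--monotone/--net-only`), strict by default.

Because the progressive criterion only tightens as δ grows, the progressive
set at a larger margin is a subset of that at a smaller one. `sweep_margins`
asserts this nesting on every run; it is also the reason stable-trend
sensitivity is non-decreasing and specificity non-increasing across the
sweep.

## Diagnostic accuracy

The 2×2 table crosses trend with 6-month outcome. Two directions are
reported, mirror images of each other:

| direction | condition positive | test positive |
|---|---|---|
| stable_predicts_success | success | stable |
| progressive_predicts_failure | failure | progressive |

Sensitivity in one direction equals specificity in the other, and PPV/NPV
swap likewise; the property suite asserts this duality on random tables.

**Confidence intervals** are exact Clopper-Pearson by default: the bounds
invert the binomial tail probabilities, equivalently Beta quantiles
(lower = Beta(α/2; k, n−k+1), upper = Beta(1−α/2; k+1, n−k)), with the
closed forms lower = 0 at k = 0, upper = 1 at k = n, and lower =
(α/2)^(1/n) at k = n. The exact method was chosen because it reproduces the
reference bounds for small counts ((α/2)^(1/4) = 0.3976 for 4/4); a Wilson
score interval is available by flag. Exact intervals are conservative —
empirical coverage sits at or above the nominal 95% — which the suite
checks against a 93.5% floor over simulated binomial draws. Computation is
delegated to `statsmodels.stats.proportion.proportion_confint`; tests
verify it against an independent bisection on exact binomial tail sums.

**Undefined metrics.** A zero denominator (e.g. NPV when no patient is
progressive) is reported as missing with a footnote, never coerced to 0 or
1, to avoid silently distorting small cohorts.

**Association test.** Uncorrected Pearson chi-square, Σ(O−E)²/E with df = 1
(`scipy.stats.chi2_contingency`, `correction=False`). Uncorrected is the
default because it is the method consistent with the reference p-value on
the >1 mmHg table (p ≈ 0.044; the Yates-corrected value is ≈ 0.107); the
correction is available by flag. The statistic is undefined when a row or
column marginal is zero, and the per-margin report then carries `None`.

**Multiplicity.** Metrics at several margins are reported without
multiple-testing adjustment, matching the source analysis; every report
carries a note saying so.

**Reporting precision.** Machine output rounds percentages to 2 d.p.;
internal values are never rounded. The text renderer
(`render_paper_tables`) uses journal-style mixed rounding (1 d.p. in the
sweep table) for side-by-side comparison.

## Synthetic cohorts

`CohortConfig` defaults encode the study conditions the analysis was
designed around:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 40 | cohort size |
| `opening_pressure_mean/sd/range` | 18.53 / 6.61 / (8, 44) mmHg | truncated normal |
| `day1_dav_mean/sd` | 6.36 / 2.46 mmHg | day-1 DAV level across patients |
| `hourly_noise_sd` | 1.0 mmHg | within-day reading noise |
| `prop_progressive` | 4/31 | progressive-archetype fraction |
| `progressive_drift` | 3.0 mmHg | total day-1→day-3 rise, split 50/50 |
| `stable_jitter` | 0.5 mmHg | stable-archetype day-to-day wobble |
| `p_failure_given_stable` | 15/27 | outcome link |
| `p_failure_given_progressive` | 1.0 | outcome link |
| `dropout_prob` | 9/40 | chance of losing whole days |

Design choices:

* **Opening pressure** is a truncated normal clipped to the range — the
  simplest law matching a reported mean, SD and range simultaneously.
* **Archetypes.** The progressive archetype rises strictly monotonically
  with the total drift split equally across the two day-to-day steps, so it
  satisfies the continuous-increase clause deterministically whenever the
  drift exceeds the margin. The stable archetype holds the day-1 level with
  uniform jitter of ±0.5 mmHg, below every margin in the default grid, so
  it can never be mislabelled in the noiseless regime.
* **Noise.** Hourly readings add independent Gaussian noise to the day
  level, floored at 0 mmHg. No anchor exists for the within-day spread of
  hourly readings; 1.0 mmHg was fixed once as a realistic transducer-level
  variation that leaves the day-level signal dominant (the SD of a DAV
  inflates only by noise²/24). Averaging 24 readings shrinks noise by
  √24 ≈ 4.9, so margins of 1–5 mmHg operate far above the noise floor.
* **Dropout** removes whole days — day 2 onward or day 3 only, with equal
  probability — because the real failure mode is catheter pull-out, an
  all-or-nothing event; single missing hours are not simulated.
* **Outcomes** are Bernoulli conditional on archetype. Deaths are not
  modelled separately; a death is a failure. The optional 1- and 3-month
  outcome columns are filled by nesting failure times so cohort-level
  success declines over follow-up (ratios chosen to emulate 62.5%/40%/35%
  at 1/3/6 months); they are descriptive only and enter no computation.
* **Seeding** is mandatory — there is no silent entropy source — and a
  fixed seed yields byte-identical output files (floats serialized at 17
  significant digits, which round-trips IEEE doubles losslessly).

What passing tests on synthetic data do **not** show: real post-ETV
pressures have autocorrelated within-day dynamics, a day-1 decline from the
opening pressure, waveform artifacts, and clinically driven (informative)
dropout; the generator draws none of these. Recovery results therefore
validate the pipeline's logic, not the clinical effect size.

## Pipeline and configuration

`RunConfig` (YAML/JSON) takes exactly one input source — `patients_path` +
`series_path`, or a `simulate` block — plus `min_readings_per_day`,
`margins` (strictly increasing, default 1–5 mmHg), `directions`,
`ci_method` (`clopper-pearson` | `wilson`), `confidence`, `out_dir`, and
`log_level`. `run_pipeline` executes ingest → DAV → classify → evaluate →
summary, writes `davs.csv`, `calls.csv`, `report.json`, `summary.json` and
`tables.txt`, logs per-stage counts to stderr with `[stage]` markers, and
embeds a hash of the analytic configuration (output location and verbosity
excluded) in every JSON artifact for provenance.

## Numerical notes and limitations

* DAV comparison is exact floating point; classification can flip at the
  machine-precision boundary for trajectories engineered to land exactly on
  a margin. Property tests avoid that measure-zero set explicitly.
* Problem sizes in the test suite (10,000-patient moment checks,
  1,000-table duality sweeps, 2,000-draw coverage runs, 150-seed dropout
  expectation) were chosen so that 3σ binomial/moment bands are decisive
  for the parameters under test while the whole suite stays in the
  tens-of-seconds range.
* The pipeline dichotomizes at fixed margins; it does not fit ROC curves
  over the continuous day-1→day-3 difference, model time-to-failure, or
  adjust for covariates (age, etiology, CSF protein).
* Cohort-level outcome rates over follow-up are emulated descriptively by
  the generator, not estimated by the pipeline.
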