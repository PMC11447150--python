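# Methods

This note documents the models, conventions and design choices behind
`hypodiary`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish about real data.

## Sensor processing

Traces are timestamped interstitial glucose (mmol/l) at a nominal 5-min
cadence. Samples are snapped to the wall-clock 5-min grid by nearest-slot
assignment (ties go to the earlier slot; two samples competing for one
slot keep the temporally closer one and the conflict is logged). Slots
with no sample within +-2.5 min are missing. **Glucose is never
interpolated**: missingness is carried through to the coverage filter
rather than smoothed over, so every downstream number is traceable to raw
readings.

An SDH episode is a maximal run of non-missing readings strictly below
3.9 mmol/l whose *covered* duration reaches 15 min. Conventions, chosen
once and fixed:

- each 5-min reading stands for 5 min of coverage, so >= 15 min is
  exactly >= 3 consecutive sub-threshold readings -- the discrete
  rendering of the consensus CGM episode definition, and exactly testable;
- a run ends at a reading >= 3.9 or at a gap longer than 10 min. Gaps of
  one or two slots are bridged (they do not break physiological
  continuity) but contribute nothing to covered duration. No bridging of
  longer gaps keeps episodes verifiable against raw data;
- severity subtype follows the nadir: SDH_3.9 (< 3.9, >= 3.0), SDH_3.0
  (< 3.0, > 2.2), SDH_2.2 (<= 2.2); "below" is strict at 3.9, and 2.2
  belongs to the deepest stratum, matching the printed inequalities.

The detector is verified against two independently formulated oracles
(an O(n^2) maximal-window enumeration and a breaker-segmentation scan)
over an exhaustive family of short traces and a thousand random 24-h
traces.

Time in range uses the inclusive 3.9-10.0 mmol/l band over non-missing
readings; the three percentages sum to 100 by construction.

## Intervals and the coverage filter

Morning (07:00) and evening (21:00) check-ins carry a 6-h response
window. For calendar date *d*: day = [morning(d), evening(d)), reported
by the evening check-in; night = [evening(d), morning(d+1)), reported by
the next morning's check-in. When a *boundary* check-in is missing its
scheduled clock time stands in; when the *reporting* check-in is missing
the interval is invalid (its exposure would have no report) -- emitted
with a reason code rather than silently dropped. Duplicate check-ins
keep the earliest submission; submissions outside the window are rejected
at load, with a config override since acceptance practice varies.

Coverage: expected slots = floor(duration / 5 min); an interval is
excluded only when strictly more than 30% of expected slots are missing
(exactly 30% is retained). The filter is monotone: adding missingness can
only invalidate.

An episode straddling the day/night boundary contributes to each interval
only its clipped portion and must retain >= 15 min of covered readings
within that interval to count -- this keeps night and day exposures
disjoint. The interval's subtype is the stratum of the lowest clipped
nadir among qualifying episodes.

## PRH coding

Reports carry a detection answer (symptomatic; asymptomatic = noticed via
the person's own glucose monitoring) and a management answer (treated /
prevented / other). Prevented episodes count as PRH present. Severe,
adjudicated episodes are flagged on input and dropped before
classification. Multiple reports in one interval are merged by an ordered
ranking -- symptomatic > asymptomatic; treated > prevented > other --
mirroring the impact gradient observed across subtypes; both rank tables
and the raw-answer maps are configurable, since coding schemes differ
between deployments.

## The outcome model

For one cohort x phase x domain cell, with scores `y_ij` (participant
*i*, interval *j* in start-time order):

    y_ij = x_ij' beta + u_i + e_ij,
    u_i ~ (0, sigma_u^2),  corr(e_ij, e_i,j+1) = rho

Estimation, in stages:

1. **Variance components** by maximum likelihood. The random-intercept
   likelihood concentrates to a one-dimensional search over the variance
   ratio lambda = sigma_u^2 / sigma_e^2 (each evaluation is a set of
   per-participant rank-one corrections), solved by bounded scalar
   minimisation with the lambda -> 0 boundary checked explicitly. With
   robust weighting off and rho = 0 the coefficients are exactly the ML
   estimates; the test suite checks agreement with an independent ML
   implementation to 1e-6 relative tolerance.
2. **Autocorrelation**, two-stage: rho is the pooled lag-1 correlation of
   level-1 residuals (marginal residual minus the shrunken participant
   mean), clipped to |rho| <= 0.9, followed by one refit under the
   updated working covariance. The AR(1) correlation is indexed by
   within-participant observation order, not calendar gaps -- a working
   correlation, not a claimed data-generating law; the cluster-robust
   standard errors below remain valid under misspecification.
3. **Robustness**: each participant block is whitened by the Cholesky
   factor of (lambda J + R(rho)), then Huber-weighted IRLS (tuning
   constant 1.345, MAD scale) runs on the whitened residuals; the plain
   ML fit is available by switching `robust=False`. Heavy-tailed and
   heteroscedastic residuals are the norm for bounded 0-10 diary scales,
   which is the reason for the robust default.

Standard errors are cluster-robust over participants. For the Huber
M-estimator the sandwich bread uses psi'(u) -- an indicator of
non-truncated residuals -- rather than the IRLS working weights c/|u|;
using the working weights understates variance noticeably (the Monte
Carlo type-I studies in the test suite are sensitive to exactly this).
A small-sample G/(G-1) factor is applied. CIs are Wald (+- 1.96 SE);
p-values are normal-based, adequate at the 200+ participant scales the
pipeline targets.

**Percent change** divides estimate and CI bounds by the model intercept,
treating the intercept as fixed; this matches the usual forest-plot
presentation and ignores intercept uncertainty (a documented
approximation -- at these sample sizes the intercept SE is an order of
magnitude smaller than the contrast SEs). Numeric covariates are
mean-centred so the intercept is the adjusted no-hypoglycaemia mean and
the percent scale is interpretable.

Bounded 0-10 outcomes are modelled linearly; the bias this induces is
*measured* by the recovery studies (clipping at the defaults attenuates a
-1.0-point effect on a mean of 7.0 by about 0.01-0.03 points) rather than
hidden.

Degenerate inputs: a single participant or a single observed exposure
level raises an estimation error; unobserved exposure levels are omitted
with a warning; covariate columns that alias (common in small cohorts)
are pruned by an incremental rank check; non-convergent IRLS returns with
an honest `converged=False`.

**Multiplicity.** The family size is (morning + evening domains) x
cohorts x model iterations; at the default design 19 x 2 x 7 = 266 and
the per-test alpha is 0.05/266 ~= 0.0002. The iteration count enters only
this arithmetic -- the package implements the final model, not the seven
historical variants. Exploratory subtype families (PRH combined levels
adjusted for SDH presence; SDH subtypes adjusted for PRH presence) are
flagged at unadjusted 0.05 and labelled as such in the output.

## The synthetic cohort

The generator's defaults are the study conditions: 274 + 320 participants,
70 days, 86% morning / 90% evening check-in completion, and night-time
excursion/reporting rates (0.248, p_detect 0.315, p_false 0.043) derived
once from the published night-time category split (72 / 17 / 3.2 / 7.8 for
A / B / C / D). Detection and false-report probabilities are shared across
phases, so the daytime split is emulated only qualitatively.

Glucose is a discretised mean-reverting process (baseline 7-9 mmol/l,
2-h reversion, stationary SD 0.8) floored at 4.5 mmol/l, with
hypoglycaemic excursions inserted as smooth dips of configured nadir
stratum and 20-50 min below-threshold duration, placed wholly inside one
realised interval with a 15-min margin. The floor means sub-threshold
glucose occurs *only* by insertion, so the generator's per-interval
category is exact ground truth -- chosen deliberately over physiological
realism, which is a non-goal. Scores follow the fitted model's own form
(domain mean + participant intercept SD 1.0 + category effect + AR(1)
residual, SD 1.2, rho 0.2) clipped to [0, 10]; default injected effects
are zero for sensor-only intervals and negative for reported
hypoglycaemia, strongest when sensor-confirmed (e.g. -0.8 points on sleep
quality for type-D nights, about -11% of its 7.2 mean). Identical
(config, seed) pairs produce byte-identical output files.

What passing tests therefore show: the processing chain recovers known
exposure labels (>= 99% with a clean sensor), the estimator is calibrated
under the model it assumes, and the whole pipeline is deterministic. What
they do not show: robustness to sensor artefacts (compression lows,
calibration drift), reactive reporting behaviour, informative missingness,
or covariate-outcome confounding -- real-data phenomena the generator
deliberately does not model.

## Monte Carlo studies and problem sizes

Calibration studies (type-I error of the type-D contrast over 200
replicates; percent-change recovery and CI coverage over 100 replicates)
run at 200 participants x 60 nights using the interval-level score
simulator: these properties concern the estimator on interval-level data,
so simulating CGM traces underneath each replicate would add nothing but
runtime. The acceptance script's pipeline demonstration uses 30 + 30
participants x 21 days -- large enough for every category to appear and
for all 19 x 2 primary models to fit, while a full run stays in seconds.

## Known limitations

- Percent-change CIs ignore intercept uncertainty (delta-method bounds
  would be marginally wider).
- The AR(1) stage estimates rho once from stage-1 residuals; rho and the
  Huber weights are not iterated jointly.
- Time-zone handling is a single fixed offset per participant; daylight
  transitions inside a study are out of scope.
- The ordered ranking used to merge multiple PRH reports is a documented,
  configurable default, not a universal standard.
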