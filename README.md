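# hypodiary

Analysis pipeline for ecological-momentary-assessment (EMA) studies of
hypoglycaemia in insulin-treated diabetes: fuse a **blinded continuous
glucose monitor** (5-min interstitial glucose, mmol/l) with **thrice-daily
app check-ins** (0-10 daily-functioning scores and person-reported
hypoglycaemia), classify every participant-night and participant-day by
hypoglycaemia exposure, and estimate how each exposure category relates to
ten domains of self-reported daily functioning with robust multilevel
regression. A seedable synthetic-cohort generator with known ground truth
makes every stage testable without access-restricted patient data.

Intended users: biostatisticians and diabetes researchers working with
CGM + diary data who need a reproducible, auditable exposure-outcome
pipeline rather than ad hoc notebook code.

## The method in brief

**Exposure.** Sensor-detected hypoglycaemia (SDH) is a maximal run of
5-min readings strictly below 3.9 mmol/l sustained for >= 15 min, with
severity subtypes by nadir: SDH_3.9 (< 3.9, >= 3.0), SDH_3.0 (< 3.0,
\> 2.2), SDH_2.2 (<= 2.2). Person-reported hypoglycaemia (PRH) comes from
morning/evening check-ins (detection: symptomatic vs asymptomatic;
management: treated / prevented / other). Morning and evening submission
times split each 24 h into a night interval (evening -> next morning) and
a day interval (morning -> evening); intervals missing their reporting
check-in, or with more than 30% of expected sensor slots missing, are
excluded. Each valid interval gets one of four categories:

| | SDH (-) | SDH (+) |
|---|---|---|
| **PRH (-)** | A (none) | B (sensor only) |
| **PRH (+)** | C (reported only) | D (both) |

**Outcome model.** For each cohort (type 1 / type 2 diabetes), phase and
functioning domain *y* (0-10, higher = better):

```
y_ij = beta_0 + beta_B B_ij + beta_C C_ij + beta_D D_ij + gamma' x_i + u_i + e_ij
u_i ~ N(0, sigma_u^2),   corr(e_ij, e_ij') = rho^|j-j'|   (AR(1) within participant)
```

fitted by profiled maximum likelihood for the variance components, a
two-stage AR(1) working-correlation adjustment, and Huber-weighted IRLS
(c = 1.345) for robustness, with cluster-robust (sandwich) standard
errors. Effects are reported as percent change from the intercept,
`100 * beta / beta_0`. The primary category family is tested at a
Bonferroni threshold `0.05 / 266 = 0.0002` (10 morning + 9 evening
domains x 2 cohorts x 7 model iterations); exploratory PRH/SDH subtype
families at unadjusted 0.05.

## Worked example

```python
from hypodiary import ModelSpec, fit_domain_model, simulate_interval_scores

df = simulate_interval_scores(
    200, 60, effects={"C": -0.4, "D": -1.0}, seed=123
).rename(columns={"score": "sleep_quality"})
res = fit_domain_model(df, ModelSpec("type1", "night", "sleep_quality"))
print(res.intercept, res.levels[-1].percent_change)
```

This simulates 200 participants x 60 nights with a known -1.0-point
type-D effect on a domain with mean 7.0 and fits the full robust model
(`examples/04_fit_models.py` prints the complete table):

```
intercept 6.95 (score points on the 0-10 scale)
AR(1) rho 0.17; 200 participants, 12000 rows
  type B: -0.050 points [-0.115, +0.015]  = -0.7% of the intercept  (p=0.13)
  type C: -0.309 points [-0.426, -0.192]  = -4.4% of the intercept  (p=2.2e-07)
  type D: -1.059 points [-1.141, -0.977]  = -15.2% of the intercept  (p=7.9e-142)
```

The type-D estimate sits near the injected truth (-1.0 points =
-14.3% of the intercept); the null type-B contrast is correctly flat.
Each `examples/` script demonstrates one capability end to end (episode
detection, interval construction, classification, modelling, the full
pipeline), and the `hypodiary` CLI exposes `simulate`, `classify`,
`model` and `run-all` over a YAML config.

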