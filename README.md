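# heartage

A heart age calculator and its surrounding analytics, built the way the
Australian national web tool works: sex-specific 10-year absolute
cardiovascular disease (CVD) risk from a Framingham-type Cox equation,
inverted to a **heart age** against an ideal-risk-factor referent, with
guideline-style input validation, population-average imputation of
unknown values, display censoring, and report rendering. Companion
modules reproduce the descriptive and chi-square analytics used to
evaluate such tools at population scale, and a seeded synthetic cohort
generator makes everything testable without any user data.

Intended users: biostatisticians and digital-health teams who want a
transparent, configurable reference implementation of a heart-age tool —
every coefficient lives in a YAML file, none in code.

## The model

For sex *s*, 10-year absolute risk is

```
risk = 1 − S0_s ^ exp(LP − LP̄_s),   LP = Σ_i β_i · x_i
```

where `x_i` are covariates (ln age, ln total cholesterol, ln HDL, ln SBP
with separate treated/untreated β, smoking, diabetes), `S0_s` the
baseline 10-year event-free survival and `LP̄_s` the population-mean
linear predictor. The shipped default transcribes the published
general-CVD Framingham lipid equations (a BMI-based office variant is
also included); lipid inputs are mmol/L and converted at
1 mmol/L = 38.67 mg/dL where the equation declares mg/dL.

**Heart age** is the age `a*` at which an *ideal* referent — non-smoker,
non-diabetic, untreated SBP 120 mmHg, total cholesterol 4 mmol/L — has
the same risk as the user:

```
ideal_risk(a*) = risk(user)   →   a* by monotone bisection on [20, 120]
```

Displayed heart age is censored to `<35` and `≥85` and categorised as
younger / equal / older than the user's current age (round half away
from zero). Unknown SBP or cholesterol is imputed from a sex × 5-year
age band table (the shipped table is a clearly labelled synthetic
placeholder); implausible cholesterol (outside 2–10.5 mmol/L) blocks
calculation with the calculator's message, while high but plausible
values (>7.5 mmol/L) add a see-your-doctor advisory without blocking.

Survey analytics use the Pearson chi-square, `Σ(O−E)²/E` with
`(r−1)(c−1)` df and no continuity correction, comparing outcome rates
between heart-age result groups.

## Worked example

```bash
$ heartage calculate --age 50 --sex female --sbp 135 --cholesterol 5.5
heart_age=65 category=older risk=0.0533
```

A 50-year-old woman with SBP 135 mmHg and total cholesterol 5.5 mmol/L
has a 5.3% 10-year risk — the same risk an ideal-risk woman would reach
at age 65, so her heart age is 65, an *older* result. With unknown
values the calculator says so in the report:

```bash
$ heartage calculate --age 54 --sex male --smoker --diabetes --family-history
heart_age=≥85 category=older risk=0.3587
```

Here SBP and cholesterol were imputed from the 50–54 male band averages;
the risk (35.9%) exceeds the ideal curve's ceiling, so the displayed
heart age is censored at ≥85. `--report` prints the full emailed-style
report, including which values used a population average and the
heart-health-check recommendation for users in the 45–75 target group.

Batch mode (`--input users.csv --out results.csv`), cohort summaries
(`heartage cohort-summary`), chi-square comparisons
(`heartage survey-compare`) and the synthetic generator
(`heartage simulate`) follow the same pattern; every run writes a JSON
manifest recording the config hash and seed.

```bash
$ heartage survey-compare --counts 538 1055 83 248
chi2=24.7294 df=1 p=6.597e-07 pct=51.00 vs 33.47
```

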