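# Methods

## Risk model

The risk engine evaluates sex-specific Cox proportional-hazards
equations of the Framingham general-CVD family:
`risk = 1 − S0^exp(LP − LP̄)` with `LP = Σ β_i x_i` over transformed
covariates. The shipped lipid configuration uses ln(age), ln(total
cholesterol), ln(HDL), ln(SBP) with separate treated/untreated betas,
smoking and diabetes indicators; the office (BMI) configuration replaces
the lipid terms with ln(BMI). Both transcribe the published equations,
including baseline survivals (e.g. 0.95012 women / 0.88936 men, lipid
variant) and the published aggregate mean linear predictors (26.1931 /
23.9802).

Design points:

- **Everything is configuration.** The deployed Australian tool applied
  unpublished recalibrations to some age/sex weightings; since those
  numbers are not public, the package treats every beta, transform,
  baseline survival and mean as YAML data so a recalibrated set drops in
  without code changes. The code never hard-codes a coefficient.
- **Mean linear predictor.** Configurations may supply per-covariate
  reference means (the mean LP is then Σ β·mean, using the untreated SBP
  beta) or the aggregate `mean_linear_predictor` directly. The defaults
  use the aggregate because that is the published quantity; per-covariate
  means for these cohorts were not republished alongside the betas.
- **Units.** User-facing lipids are mmol/L (Australian practice);
  1 mmol/L = 38.67 mg/dL is applied before the log transform when the
  equation declares mg/dL. SBP is mmHg, height cm, weight kg.
- **Family history** is collected but enters only through a configurable
  hazard multiplier, default 1.0 (no effect), because the deployed tool
  never stated how (or whether) it scored the item. Setting it to a
  literature-based relative risk is a one-line config change.
- **HDL** is never user-entered; it always comes from the imputation
  table (or an ideal value for the referent). **BMI** is computed from
  height and weight but only consumed when the active equation names it.

## Heart-age conversion

Heart age solves `ideal_risk(a*) = risk(user)` where the ideal referent
is a non-smoker, non-diabetic of the user's sex with untreated SBP
120 mmHg and total cholesterol 4 mmol/L (the Australian ideal levels);
the referent's HDL (1.3 mmol/L) and BMI (22.5 kg/m²) are package
defaults, configurable, since no published values exist for them.

The solver is monotone bisection on age over [20, 120] years. Because
risk is strictly increasing in the linear predictor, the root is found
on the LP scale — identical root, but immune to floating-point
saturation of `risk → 1` for extreme profiles. The bisection tolerance
is 1e-9 years (runtime is unaffected; ~60 cheap evaluations), which
keeps the re-evaluated ideal risk at the solution within ~1e-12 of the
user's risk. A closed-form inversion
`a* = exp((LP_user − LP_ideal,non-age)/β_age)`, valid when the only age
term is `β_age·ln(age)`, is retained purely as a test oracle.

Risks outside the bracket's ideal-risk range clamp to the nearer bound
with a `bracket_censored` flag rather than raising: such profiles are
exactly the ones the display censoring exists for. Displayed heart age
rounds half away from zero to whole years, then censors to `<35` /
`≥85`; the raw value is retained. The younger/equal/older category
compares the rounded heart age with the integer current age; a tie is
"equal".

Validation follows the deployed tool's split: implausible values
(cholesterol outside 2–10.5 mmol/L) are range errors that block
calculation; plausible-but-high values (cholesterol > 7.5 mmol/L) add a
high-risk advisory and the calculation proceeds. The SBP plausibility
range (70–250 mmHg) and high-risk threshold (180 mmHg) were never
published; both are config entries flagged as package defaults. Ages
outside the 35–75 target range get an eligibility warning but are still
computed, clamping to the edge imputation bands.

The imputation table (sex × 5-year band → mean SBP, total cholesterol,
HDL) shipped in the default configs is a plainly labelled synthetic
placeholder with plausible Australian adult values; the deployed tool
used 2011–12 National Health Survey means, which are not republished
here. Nothing in the test suite or acceptance run depends on the
placeholder's specific numbers.

## Survey statistics

Group comparisons use the Pearson chi-square without continuity
correction — the form that reproduces all nine published statistics from
their published counts (scipy's `chi2_contingency` underneath; the test
suite checks it against a hand-written Σ(O−E)²/E oracle on random
tables). A Yates-corrected option exists but is off by default. Any
zero expected count raises a degenerate-table error. The 5-point
emotion items ("a great deal / a lot") are taken as precomputed
booleans per respondent; the raw scale was never published.

One published statistic (lost weight, 5.4) is the 1-dp half-up rounding
of an intermediate 2-dp display (5.347 → 5.35 → 5.4); the tests mirror
that two-stage rounding chain when comparing to printed values.

The deterministic survey fixture assigns outcomes by exact count within
each heart-age category (1055 older / 155 younger / 93 equal, n=1303),
rotating the assignment offset per outcome so columns are not perfectly
collinear. The "reduced or quit smoking" row keeps its published yes
counts (19 / 0); its published percentage used the 39 smokers as
denominator, whereas the comparison table reports percentages on the
group totals — counts, not that percentage, are the reproduced quantity.

## Cohort analytics

Summaries report counts with percentages rounded to 2 dp, age mean and
sample (n−1) SD, and the 35–44 / 45–54 / 55–64 / 65–75 age bands
(inclusive bounds; the banding is taken as 45–54 / 65–75 where source
phrasings differ by one year). The heart-age gap summary uses the raw,
uncensored heart age minus chronological age, with sample SD; the
published variant (population vs sample SD) is not stated, and no
acceptance quantity hinges on the choice.

## Synthetic cohorts

The generator emulates the published aggregate structure, not real
users:

- Bernoulli marginals per risk factor (defaults: the anonymous-sample
  rates, e.g. smoker 9.83%, female 61.29%), drawn independently — joint
  correlations among risk factors were never reported, and this is the
  generator's main departure from real data. Tests that pass on these
  cohorts therefore validate the pipeline mechanics and marginal
  behaviour, not joint-distribution realism.
- Truncated-normal age (mean 49.37, SD 11.79, bounds 35–75), SBP
  (130/17, 70–250 mmHg), total cholesterol (5.4/1.0, 2–10.5 mmol/L) and
  BMI (27.5/5.0), with sex-specific heights (164/178 ± 7 cm) converting
  BMI to weight. Values are present only when the matching "known" flag
  is drawn true.
- The engagement funnel (anonymous → report → survey; default rates
  30,279/361,044 and 1303/30,279) selects each stage by a logistic
  weighting whose covariate coefficients (older, more risk-aware,
  less likely smokers) reproduce the qualitatively documented selection
  gradient; the intercept is solved numerically so the expected stage
  size always matches the configured rate. The functional form is a
  package choice — only the direction of the gradient is documented.
- A single integer seed drives independent substreams (user generation,
  funnel, survey outcomes), so any stage regenerates identically on its
  own.

Sizes used in the checked runs: marginal recovery uses n=30,000 per
seed across 100 (test) / 200 (acceptance script) sub-seeds — with eight
marginals checked at 3 binomial SDs the per-seed all-pass probability is
≈0.98, comfortably above the 0.95 criterion; the funnel simulation runs
at the full published anonymous-stage size (361,044).

## Known limitations

- The default coefficients are the published general-CVD equations, not
  the deployed tool's privately recalibrated weightings; individual
  results will differ from the live calculator.
- The imputation table is a placeholder; replace it with survey-derived
  means for any real use.
- Synthetic cohorts have independent risk factors and a parametric
  engagement model; they cannot reproduce population-level outcome
  statistics (e.g. the observed mean heart-age gap), which depend on the
  joint distribution of real users.
- The tool is a risk-communication format, not a clinical assessment;
  absolute-risk decisions belong with guideline-based assessment by a
  clinician.
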