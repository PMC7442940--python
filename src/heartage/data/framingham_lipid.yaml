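# Default model configuration: lipid-based general-CVD risk equations.
#
# The betas, baseline 10-year survivals and mean linear predictors are the
# published sex-specific general cardiovascular disease Cox equations
# (lipid profile variant, mg/dL lipid units).  The deployed Australian
# calculator applied unpublished adjustments to some age/sex weightings;
# those cannot be reproduced, so this file is explicitly replaceable —
# point --config at a recalibrated copy to swap every number below.
name: framingham-general-cvd-lipid
lipid_units: mg/dL
family_history_hazard_multiplier: 1.0

equations:
  female:
    baseline_survival: 0.95012
    mean_linear_predictor: 26.1931
    terms:
      - {covariate: age, transform: log, beta: 2.32888}
      - {covariate: total_cholesterol, transform: log, beta: 1.20904}
      - {covariate: hdl_cholesterol, transform: log, beta: -0.70833}
      - {covariate: sbp, transform: log, beta: 2.76157, beta_treated: 2.82263}
      - {covariate: smoker, transform: identity, beta: 0.52873}
      - {covariate: diabetes, transform: identity, beta: 0.69154}
  male:
    baseline_survival: 0.88936
    mean_linear_predictor: 23.9802
    terms:
      - {covariate: age, transform: log, beta: 3.06117}
      - {covariate: total_cholesterol, transform: log, beta: 1.12370}
      - {covariate: hdl_cholesterol, transform: log, beta: -0.93263}
      - {covariate: sbp, transform: log, beta: 1.93303, beta_treated: 1.99881}
      - {covariate: smoker, transform: identity, beta: 0.65451}
      - {covariate: diabetes, transform: identity, beta: 0.57367}

# The referent used for heart-age conversion: non-smoker, non-diabetic,
# untreated SBP 120 mmHg, total cholesterol 4 mmol/L (Australian ideal
# levels); HDL and BMI ideals are package choices (not printed anywhere).
ideal:
  sbp: 120.0
  total_cholesterol: 4.0
  hdl_cholesterol: 1.3
  bmi: 22.5

heart_age_bounds:
  display_min: 35      # results below round to "<35"
  display_max: 85      # results at or above round to ">=85"
  solver_min: 20.0     # bisection bracket, years
  solver_max: 120.0
  tol_years: 1.0e-9

validation:
  total_cholesterol: {min: 2.0, max: 10.5, high_risk: 7.5}   # mmol/L
  # SBP plausibility and high-risk thresholds were not published for the
  # deployed tool; these defaults are package choices.
  sbp: {min: 70.0, max: 250.0, high_risk: 180.0}             # mmHg
  age: {min: 35, max: 75}                                    # years

# SYNTHETIC placeholder imputation table.  The deployed tool used sex- and
# 5-year-age-band population means from the 2011-12 National Health Survey;
# those exact values are not republished here, so these are plausible
# Australian adult values in the same structure.  Replace the block to use
# survey-derived means.  Bands tile ages 35-75; the last band includes 75.
imputation:
  source: synthetic placeholder (replace with survey-derived means)
  bands:
    female:
      35: {sbp: 117.0, total_cholesterol: 5.0, hdl_cholesterol: 1.5}
      40: {sbp: 119.0, total_cholesterol: 5.2, hdl_cholesterol: 1.5}
      45: {sbp: 122.0, total_cholesterol: 5.4, hdl_cholesterol: 1.5}
      50: {sbp: 125.0, total_cholesterol: 5.6, hdl_cholesterol: 1.5}
      55: {sbp: 129.0, total_cholesterol: 5.8, hdl_cholesterol: 1.5}
      60: {sbp: 133.0, total_cholesterol: 5.9, hdl_cholesterol: 1.5}
      65: {sbp: 137.0, total_cholesterol: 5.9, hdl_cholesterol: 1.5}
      70: {sbp: 140.0, total_cholesterol: 5.8, hdl_cholesterol: 1.5}
    male:
      35: {sbp: 122.0, total_cholesterol: 5.2, hdl_cholesterol: 1.2}
      40: {sbp: 124.0, total_cholesterol: 5.4, hdl_cholesterol: 1.2}
      45: {sbp: 127.0, total_cholesterol: 5.5, hdl_cholesterol: 1.2}
      50: {sbp: 130.0, total_cholesterol: 5.6, hdl_cholesterol: 1.2}
      55: {sbp: 133.0, total_cholesterol: 5.6, hdl_cholesterol: 1.2}
      60: {sbp: 136.0, total_cholesterol: 5.5, hdl_cholesterol: 1.2}
      65: {sbp: 139.0, total_cholesterol: 5.4, hdl_cholesterol: 1.2}
      70: {sbp: 141.0, total_cholesterol: 5.3, hdl_cholesterol: 1.2}
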