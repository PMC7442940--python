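# Office-based (non-laboratory) general-CVD risk equations: BMI replaces
# the lipid terms, so no cholesterol values are needed.  Same published
# source family as the default lipid configuration.
name: framingham-general-cvd-bmi
lipid_units: mg/dL
family_history_hazard_multiplier: 1.0

equations:
  female:
    baseline_survival: 0.94833
    mean_linear_predictor: 26.0145
    terms:
      - {covariate: age, transform: log, beta: 2.72107}
      - {covariate: bmi, transform: log, beta: 0.51125}
      - {covariate: sbp, transform: log, beta: 2.81291, beta_treated: 2.88267}
      - {covariate: smoker, transform: identity, beta: 0.61868}
      - {covariate: diabetes, transform: identity, beta: 0.77763}
  male:
    baseline_survival: 0.88431
    mean_linear_predictor: 23.9388
    terms:
      - {covariate: age, transform: log, beta: 3.11296}
      - {covariate: bmi, transform: log, beta: 0.79277}
      - {covariate: sbp, transform: log, beta: 1.85508, beta_treated: 1.92672}
      - {covariate: smoker, transform: identity, beta: 0.70953}
      - {covariate: diabetes, transform: identity, beta: 0.53160}

ideal:
  sbp: 120.0
  total_cholesterol: 4.0
  hdl_cholesterol: 1.3
  bmi: 22.5

heart_age_bounds:
  display_min: 35
  display_max: 85
  solver_min: 20.0
  solver_max: 120.0
  tol_years: 1.0e-9

validation:
  total_cholesterol: {min: 2.0, max: 10.5, high_risk: 7.5}
  sbp: {min: 70.0, max: 250.0, high_risk: 180.0}
  age: {min: 35, max: 75}

# Same synthetic placeholder table as the lipid configuration; only HDL is
# consumed when the BMI equations are active (for report completeness).
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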