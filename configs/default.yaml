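# Example configuration covering every key, at the study-default values.
# Any key may be omitted; these are the built-in defaults.

seed: 0
study_end: "2018-04-03"

# Overrides for the synthetic-cohort generator (used by the `simulate`
# stage).  Field names follow gencompete.simulate.SimulationConfig.
simulation:
  n_drugs: 982
  n_classes: 30
  class_effect_sd: 0.3
  monograph_product_prev: 0.403
  monograph_substance_prev: 0.749
  frac_monograph_before_first: 0.51
  true_or_any_generic: 0.64
  true_irr_count: 1.53
  true_hr_gap23: 0.99
  baseline_count_mean: 1.7
  count_dispersion: 1.0
  gap_time_scale_days: 245.0
  censor_date: "2018-04-03"
  price_noise_sd: 0.1
  outcome_model: count          # count | logistic
  exposure_timing: before_first # before_first | before_second | before_third
  timeline_model: count_driven  # count_driven | gap_hazard
  covariate_effects: true
  nda_start: "1982-01-01"
  nda_end: "2004-12-31"
  panel_years: [1997, 2016]

# Eligibility cascade: ordered filters with their parameters.
# null means the built-in default order shown here.
cascade:
  - name: pre_1982
    cutoff_year: 1982
  - name: generic_or_loe_before_cutoff
    cutoff_year: 1998
  - name: monograph_before_nda
  - name: under_patent
  - name: no_sales_match
  - name: no_therapeutic_class
  - name: otc_or_discontinued

models:
  cov_struct: exchangeable      # exchangeable | independence

savings:
  years: [2015, 2016]
  curve_file: null              # CSV with columns n_generics, relative_price;
                                # null uses the illustrative built-in curve
  exposure: before_first        # which markets the counterfactual applies to

# Real input files; null means the simulate stage's outputs in --out-dir.
inputs:
  products: null
  products_dialect: orange_book # orange_book | csv
  monographs: null
  sales: null
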