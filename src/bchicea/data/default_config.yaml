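# Default run configuration. Every value here is the base-case setting;
# fixture paths of null resolve to the CSVs packaged with the library.
fixtures:
  study_summaries: null
  costs: null
  adverse_events: null
  life_table: null

model:
  start_age: 47.15            # enrolment-weighted mean age of the two intervention cohorts
  horizon_years: 10           # base case; null = lifetime
  cycle_months: 3
  discount_annual: 0.05
  sp_upgrade_interval_years: 5
  wtp: 50000
  include_boundary_upgrade: true
  reimplant_includes_device: false
  baseline_utility: 0.67      # pooled pre-operative utility, applied to both arms

utilities:
  osia: {gain_3m: 0.09, gain_6m: 0.09}
  baha: {gain_3m: 0.06, gain_6m: 0.06}   # 3-month change unreported; assumed equal to 6-month

reoperation_split:
  osia: {revision: 0.0, explant: 1.0, reimplant: 0.0}
  baha: {revision: 0.0, explant: 0.5, reimplant: 0.5}

psa:
  n_draws: 1000
  seed: 20221006
  cost_cv: 0.10               # gamma SE as a fraction of the mean
  utility_gain_se_mode: ten_percent   # "ten_percent" or "study"
  wtp_grid: [0, 5000, 10000, 15000, 20000, 25000, 30000, 35000, 40000,
             45000, 50000, 55000, 60000, 65000, 70000, 75000, 80000,
             85000, 90000, 95000, 100000]

output_dir: results
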