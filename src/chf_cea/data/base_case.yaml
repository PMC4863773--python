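# Base-case parameter pack: eplerenone vs usual care, NYHA class II chronic
# heart failure, Australian healthcare system perspective, 2014 AUD.
#
# SYNTHETIC STAND-INS: the placebo transition table (CSV below, filename
# flagged "standin_synthetic") and the age trend are not transcriptions of
# the source trial's per-class table or the national mortality table.  The
# table is a plausible construction consistent with the trial's printed
# aggregate statistics (placebo primary-outcome incidence ~25.9% over a
# 21-month median follow-up; NYHA IV row tied to NYHA III by assumption);
# the age trend is a smooth ~9%/year exponential mortality growth
# normalized to 1.0 at the baseline age of 68.  Replace both with
# transcribed values for exact reproduction of the published results.
model:
  horizon: 10
  start_state: II
  cohort_size: 1000
  baseline_age: 68
  death_hr_mode: cv-only
  age_trend_order: before-treatment
  accrual: cycle-start
transition_table:
  csv: transition_table_standin_synthetic.csv
  provenance: weighted-average
hazard_ratios:
  hf_hosp: {point: 0.58, lo: 0.47, hi: 0.70}
  cv_death: {point: 0.76, lo: 0.61, hi: 0.94}
  all_cause_death: {point: 0.76, lo: 0.62, hi: 0.93}
mixture:
  I: 0.0
  II: 0.437
  III: 0.937
  IV: 0.937
utilities:
  I: 0.815
  II: 0.720
  III: 0.590
  IV: 0.508
costs:
  background_annual: {I: 151, II: 175, III: 226, IV: 242}
  hf_hosp_event: 7136
  cvd_death_admission: 3642
  death_in_hospital_fraction: 0.5
  death_event_unit: 1821      # consistency-checked: 0.5 x 3642
  eplerenone_annual: 1374
  epl_monitor_first_cycle: 35.60
  epl_monitor_annual: 71.20
  spiro_annual: 45.29
  spiro_monitor_annual: 71.20
  hosp_events_per_cycle_cap: 1
discount:
  rate: 0.05
  start_cycle: 2
age_trend:
  kind: exponential-standin
  annual_growth: 0.09
  baseline_age: 68
  max_age: 110
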