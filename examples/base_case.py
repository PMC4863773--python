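"""Base-case analysis: eplerenone vs usual care over 10 years.

Runs the shipped parameter pack through the Markov cohort model and prints
per-arm discounted outcomes, the incremental economics, and the event
differences per 1000 patients.  The ICERs answer: how many 2014 Australian
dollars does each extra (quality-adjusted) life-year bought by adding
eplerenone cost, compared with usual care where many patients already take
spironolactone?
"""

from chf_cea import ArmLabel, base_case_parameters, event_diff, icer, run_arms

cfg = base_case_parameters()
arms = run_arms(cfg)
eg, ucg = arms[ArmLabel.EG], arms[ArmLabel.UCG]

print(f"{'':22s}{'eplerenone':>12s}{'usual care':>12s}")
print(f"{'life-years (disc.)':22s}{eg.ly_disc:12.2f}{ucg.ly_disc:12.2f}")
print(f"{'QALYs (disc.)':22s}{eg.qaly_disc:12.2f}{ucg.qaly_disc:12.2f}")
print(f"{'total cost (AUD)':22s}{eg.cost_disc:12.0f}{ucg.cost_disc:12.0f}")
print(f"{'hospitalizations/1000':22s}{eg.hospitalizations_per_1000:12.0f}"
      f"{ucg.hospitalizations_per_1000:12.0f}")
print(f"{'deaths/1000':22s}{eg.deaths_per_1000:12.0f}"
      f"{ucg.deaths_per_1000:12.0f}")

r = icer(ucg, eg)
ev = event_diff(ucg, eg)
print()
print(f"incremental cost   : {r.delta_cost:8.0f} AUD per person")
print(f"incremental LY     : {r.delta_ly:8.3f} years")
print(f"incremental QALYs  : {r.delta_qaly:8.3f}")
print(f"ICER               : {r.icer_per_yols:8.0f} AUD per year of life saved")
print(f"                     {r.icer_per_qaly:8.0f} AUD per QALY gained")
print(f"events averted/1000: {ev.hospitalizations_averted_per_1000:.0f} "
      f"hospitalizations, {ev.deaths_averted_per_1000:.0f} deaths "
      f"(NNT {ev.nnt_hosp_display} and {ev.nnt_death_display})")
print()
print("An ICER below a willingness-to-pay threshold (commonly 50,000 AUD)")
print("marks the intervention as cost-effective at that threshold.")
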