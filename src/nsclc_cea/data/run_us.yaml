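# Run configuration: first-line nonsquamous NSCLC, US payer perspective.
# Economic inputs come from the shipped US table (prices per mg, monitoring,
# PD-L1 test, subsequent therapy, supportive care, AE management, utilities)
# and can be overridden under `economic_overrides`.
country: US
horizon_years: 20.0
half_cycle_correction: false

# Overall OS/PFS curves per arm.  Illustrative Weibull fits calibrated to
# the published trial summaries (combination arm: median PFS 8.8 months,
# 12-month OS 69.2%; chemotherapy arm: median PFS 4.9 months, 12-month OS
# 49.4%); replace with your own fitted parameters for a real analysis.
curves:
  chemo:
    os: {family: weibull, shape: 1.2, scale: 16.06}
    pfs: {family: weibull, shape: 1.3, scale: 6.50}
  combo:
    os: {family: weibull, shape: 1.2, scale: 27.60}
    pfs: {family: weibull, shape: 1.3, scale: 11.66}

# Illustrative PD-L1-stratum time multipliers (accelerated-failure-time
# rescaling of the arm curves).  The combination's benefit is concentrated
# in PD-L1-positive tumors; the prevalence-weighted mean multiplier is ~1.
subgroup_multipliers:
  combo: {lt1: 0.45, pd1to49: 1.10, ge50: 1.40}
  chemo: {lt1: 1.0, pd1to49: 1.0, ge50: 1.0}

strategies:
  - {name: all_chemo, kind: all_chemo}
  - {name: all_combo, kind: all_combo}
  - {name: test_1pct, kind: test_guided, cutoff: 1pct}
  - {name: test_50pct, kind: test_guided, cutoff: 50pct}

# US price-reduction scenarios: pembrolizumab at 85% and 60% of list price.
scenarios:
  - {name: pembro_minus_15, multipliers: {pembrolizumab: 0.85}}
  - {name: pembro_minus_40, multipliers: {pembrolizumab: 0.60}}

psa: {n: 1000, seed: 20200116}
wtp_grid: {start: 0, stop: 200000, step: 2000}
output_dir: out/us
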