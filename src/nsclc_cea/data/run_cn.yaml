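# Run configuration: first-line nonsquamous NSCLC, Chinese payer perspective.
# Prices were converted to USD at 6.7 CNY/USD; the pembrolizumab charity
# donation schedule (5 paid + 5 donated, then alternating 3 + 3) is active.
country: CN
horizon_years: 20.0
half_cycle_correction: false

# Illustrative Weibull fits calibrated to the published trial summaries;
# see run_us.yaml for details.
curves:
  chemo:
    os: {family: weibull, shape: 1.2, scale: 16.06}
    pfs: {family: weibull, shape: 1.3, scale: 6.50}
  combo:
    os: {family: weibull, shape: 1.2, scale: 27.60}
    pfs: {family: weibull, shape: 1.3, scale: 11.66}

subgroup_multipliers:
  combo: {lt1: 0.45, pd1to49: 1.10, ge50: 1.40}
  chemo: {lt1: 1.0, pd1to49: 1.0, ge50: 1.0}

strategies:
  - {name: all_chemo, kind: all_chemo}
  - {name: all_combo, kind: all_combo}
  - {name: test_1pct, kind: test_guided, cutoff: 1pct}
  - {name: test_50pct, kind: test_guided, cutoff: 50pct}

# Chinese price-reduction scenario: pembrolizumab at 50% of list price,
# with the donation schedule still applied on top.
scenarios:
  - {name: pembro_minus_50, multipliers: {pembrolizumab: 0.50}}

psa: {n: 1000, seed: 20200116}
wtp_grid: {start: 0, stop: 200000, step: 2000}
output_dir: out/cn
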