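# nsclc-cea

A cost-effectiveness modelling package for first-line treatment of
metastatic nonsquamous non-small-cell lung cancer (NSCLC) without
EGFR/ALK alterations, from the US and Chinese public-payer
perspectives. It compares three strategies on discounted cost and
quality-adjusted life years (QALYs):

1. **chemotherapy for all** (pemetrexed + carboplatin/cisplatin),
2. **pembrolizumab + chemotherapy for all**, and
3. **PD-L1 test-guided therapy** — patients whose tumor proportion
   score clears a 1% or 50% cutoff receive the combination, the rest
   receive chemotherapy.

It is aimed at health-economics researchers who want a tested, scriptable
alternative to spreadsheet/TreeAge implementations of this class of model.

## The model

A three-state Markov cohort model (progression-free `PFS`, progressed
`PD`, `Death`) runs on 3-week cycles over a 20-year horizon with 3%
annual discounting. State occupancy is read off parametric survival
curves in the partitioned-survival-consistent way:

```
PFS(t) = S_PFS(t),   Death(t) = 1 − S_OS(t),   PD(t) = S_OS(t) − S_PFS(t)
```

with Weibull `S(t) = exp(−(t/λ)^k)` or log-logistic
`S(t) = 1/(1 + (t/λ)^k)` curves (shape `k`, scale `λ` in months).
Curves can be fitted from digitized Kaplan–Meier coordinates plus
numbers-at-risk via pseudo-IPD reconstruction (uniform-censoring
interval counts, then interval-censored maximum likelihood, validated
by r² against the digitized curve).

Costs cover drug acquisition under BSA/weight dosing (4 induction
cycles, pembrolizumab capped at 35 cycles, the Chinese 5+5 / 3+3
charity donation schedule), monitoring, adverse-event management, the
one-time PD-L1 test, and post-progression subsequent therapy vs
supportive care. Economics outputs are incremental cost-effectiveness
ratios (ICER = ΔC/ΔE), strict and extended dominance on the efficiency
frontier, and net monetary benefit (NMB = WTP·E − C). Uncertainty is
handled by one-way deterministic sensitivity analysis (tornado),
probabilistic sensitivity analysis (beta/gamma/lognormal
moment-matched draws), and cost-effectiveness acceptability curves.

## Worked example

```bash
nsclc-cea run --config src/nsclc_cea/data/run_us.yaml --out out/us
```

prints the base-case incremental table for the shipped US
configuration (illustrative survival curves calibrated to the trial's
published summary statistics; the original fitted parameters are not
public):

```
  strategy          cost     qaly comparator    delta_cost  delta_qaly           icer
 all_chemo 142278.675638 0.682289       None           NaN         NaN           None
 all_combo 293131.961400 1.142905  all_chemo 150853.285762    0.460616  327503.531942
 test_1pct 284075.157356 1.172644  all_chemo 141796.481718    0.490355  289171.026817
 test_1pct 284075.157356 1.172644  all_combo  -9056.804044    0.029739      dominated
test_50pct 227600.683827 0.990129  all_chemo  85322.008188    0.307840  277163.511578
test_50pct 227600.683827 0.990129  all_combo -65531.277573   -0.152776  428937.612153
```

Reading it: treating everyone with the combination costs an extra
$150,853 for 0.46 extra QALYs vs chemotherapy (ICER ≈ $327,504/QALY —
far above the $100,000/QALY US threshold under these illustrative
curves). The 1% test-guided strategy is cheaper *and* more effective
than treating everyone with the combination, so the treat-all
combination row against it is labelled `dominated`.

Other subcommands: `simulate` (synthetic two-arm trial + digitized
exports), `fit` (pseudo-IPD reconstruction + parametric fitting),
`dsa`, `psa`, `ceac`, `scenarios` (price reductions). Python API
mirrors the CLI; see the module docstrings and `docs/methods.md`.

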