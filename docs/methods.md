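# Methods

This note documents the model, its assumptions, the defaults shipped
with the package, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model structure

The cohort model has three health states — progression-free (PFS),
progressed disease (PD), and death — evaluated on 3-week cycles.
Months are defined through the mean Gregorian month (30.4375 days), so
one cycle is 21/30.4375 ≈ 0.6899 months; a 20-year horizon is 348
cycles. Occupancy is derived from the arm's overall-survival (OS) and
progression-free-survival (PFS) curves in the
partitioned-survival-consistent way: `PFS(t) = S_PFS(t)`,
`Death(t) = 1 − S_OS(t)`, `PD(t) = S_OS(t) − S_PFS(t)`. This is
equivalent to a time-inhomogeneous Markov chain whose per-cycle
transition probabilities `p_k = 1 − S((k+1)Δ)/S(kΔ)` are read off the
two curves, and it reproduces the input curves by construction (the
test suite checks the chained product to 1e−9). Where independently
fitted extrapolations cross, PFS occupancy is clamped to OS and the
number of clamped cycles logged.

Accrual is TreeAge-style state-at-cycle-start with no half-cycle
correction by default; a flag averages start/end occupancy instead.
Discounting (3%/year for both costs and QALYs) is applied at cycle
start as `(1+r)^(−t/12)` — per-cycle, not continuous; at 3% over a
20-year horizon the difference from mid-cycle or continuous conventions
is well under 1%. The horizon default of 20 years is a pragmatic
"lifetime": a convergence check warns when more than 0.5% of the cohort
is still alive at the end.

## Survival curves

Two parametric families are supported, parameterized explicitly because
rival conventions are a classic silent-failure source:

* Weibull: `S(t) = exp(−(t/scale)^shape)`
* log-logistic: `S(t) = 1/(1 + (t/scale)^shape)`

`scale` is in months; the log-logistic scale equals the median. The
shipped configs use illustrative Weibull curves calibrated to the
trial's published summary statistics (combination arm: median PFS
8.8 months, 12-month OS 69.2%; chemotherapy arm: 4.9 months, 49.4%)
with mildly increasing hazards (PFS shape 1.3, OS shape 1.2); the
original fitted parameters live in an unavailable supplement, so any
per-curve family/parameter choice can be supplied through the config.

## Pseudo-IPD reconstruction and fitting

Digitized KM coordinates plus numbers-at-risk are converted to interval
event/censoring counts under the standard assumption that censoring is
uniform in time within each at-risk interval. Within an interval the
total censored count has a closed-form solution (the implied number at
risk at the interval end is affine in it); censorings are applied after
each sub-interval's events, which makes the KM curve implied by the
counts match the digitized probabilities exactly (telescoping product —
tested to 1e−6). Counts are fractional and the reconstruction is
deterministic. Survivors past the last digitized point are
administratively censored there, so events + censorings equal the
initial cohort.

Fitting maximizes an interval-censored likelihood — events contribute
`S(t_k) − S(t_{k+1})` over their digitized sub-interval, censorings
contribute `S(t)` — via Nelder–Mead on log(shape), log(scale). This is
more standard and more testable than the least-squares regression
variant sometimes used with this reconstruction; the r² of predicted vs
digitized survival is still reported for validation, and family
selection picks the higher r², breaking ties toward Weibull. Both arms
and endpoints are fitted independently (no shared-shape constraint); a
shared-shape mode is not provided.

Digitized inputs are validated strictly (monotone probabilities,
non-increasing at-risk counts); sub-threshold digitization jitter is
clipped to a monotone sequence with a logged warning.

## Costs

All amounts are USD; Chinese prices were converted at the fixed rate of
6.7 CNY/USD before entry. The US/China input tables (unit prices per
mg, monitoring, PD-L1 test, subsequent-therapy cycle costs, supportive
care, adverse-event management, utilities, with low/high sensitivity
ranges) ship as `default_inputs("US"|"CN")`.

* **First-line dosing** (every 3 weeks): pembrolizumab 200 mg flat,
  pemetrexed 500 mg/m², cisplatin 75 mg/m²; carboplatin is dosed at
  AUC 5 by the Calvert formula, which needs a renal function value the
  source analysis never states — the default is a fixed 750 mg
  (AUC 5 × (GFR 125 + 25) mL/min), configurable, with a per-cycle cost
  impact of at most a few tens of dollars. Reference body size: BSA
  1.84 m² / 71.4 kg (US), 1.72 m² / 65 kg (China). The platinum split
  is configurable, default 50/50 carboplatin/cisplatin.
* **Schedule**: 4 induction cycles (platinum + pemetrexed, plus
  pembrolizumab in the combination arm), then maintenance pemetrexed
  (both arms) with pembrolizumab up to 35 cycles (≈ 24 months) in the
  combination arm. Monitoring cost accrues in PFS (on-treatment)
  cycles only. Premedication is a single optional per-cycle add-on,
  default 0.
* **China donation schedule**: patients pay pembrolizumab cycles 1–5,
  receive donated drug cycles 6–10, then alternate 3 paid / 3 donated
  until treatment stops. In the halved-price scenario the donation
  still applies on top of the reduced price (a flag disables stacking).
  The donation is modelled for first-line acquisition only; the
  post-progression crossover cost is a flat per-cycle config value.
* **Adverse events**: grade ≥3 anemia, neutropenia and thrombocytopenia
  management costs are weighted by per-patient incidences and spread
  over the induction cycles. The incidences are *illustrative
  placeholders* (the source table prices AE management but prints no
  incidences) and sit in the config.
* **Post-progression**: a proportion of patients (0.542 combination
  arm, 0.565 chemotherapy arm) receives subsequent therapy each PD
  cycle, the rest supportive care. The composition is a configurable
  mixture; defaults are 100% pembrolizumab crossover after
  chemotherapy and 100% docetaxel after the combination. Checkpoint
  inhibitors as subsequent therapy are capped at 35 cycles; because a
  cohort model without tunnel states cannot track time since
  progression, the cap is applied to the model cycle index, which
  upper-bounds the true exposure. After the cap the capped share
  accrues supportive care.
* **PD-L1 test**: charged once per patient at model entry, in
  test-guided strategies only, undiscounted (t = 0).
* The China nivolumab subsequent-therapy row in the source table
  prints a point value (2689) with an inconsistent range; the shipped
  default keeps the point value and uses ±20% as its range.

## Strategies and economics

A test-guided strategy is the prevalence-weighted mixture
(PD-L1 <1%: 32.87%, 1–49%: 32.18%, ≥50%: 34.95%) of per-stratum arm
evaluations plus the test cost; the test is treated as perfectly
accurate. Subgroup survival enters as per-(arm, stratum)
accelerated-failure-time multipliers on the overall curves. The
shipped multipliers (combination arm 0.45 / 1.10 / 1.40 across the
three strata, chemotherapy 1.0 everywhere) are *illustrative*: they
concentrate the combination's benefit in PD-L1-positive tumors, keep
the prevalence-weighted mean multiplier near 1, and reproduce the
published qualitative pattern in which the test-guided strategies are
cheaper and more effective than treating everyone with the
combination. They are not fitted subgroup curves.

Incremental analysis sorts strategies by cost, flags strict dominance
(no dearer and no less effective, one strict), removes extended
dominance iteratively (a sequential ICER at least as high as the next
one; exactly collinear options are kept), and reports sequential ICERs
along the frontier, which are strictly increasing by construction.
Publication-style tables additionally report each strategy against the
chemotherapy reference and against the treat-all combination; in those
rows the dominance label follows the publication convention of
describing the *comparator's* fate. The "weak dominance" wording used
in this literature for the published combination-vs-test rows is, by
the printed signs, strict dominance; both labels are computed and
reported separately. ICERs are never rounded internally.

## Sensitivity analysis

One-way DSA sets each parameter to its low/high bound (95% CI where
published, ±20% otherwise) with all else at base; entries are sorted by
bar width and dominance outcomes carried as labels. Setting a
parameter to its base value reproduces the base-case ICER
bit-identically (tested).

PSA samples all parameters independently per draw: beta for
utilities/proportions/prevalences, gamma for costs and prices,
lognormal for survival-curve shape/scale (±20% unless CIs are given).
Hyperparameters are moment-matched with mean = base and
sd = (high − low)/3.92, i.e. the range is read as a 95% interval — the
source analysis does not state its range-to-distribution mapping, so
this conventional choice is declared here. An infeasible beta variance
is clipped below m(1−m) with a logged warning. The three prevalence
weights are renormalized to sum to 1 after sampling. No correlation
structure is imposed. Default: 1000 draws, fixed seed, WTP grid 0 to
200,000 in steps of 2,000. CEACs assign each draw to the
maximal-net-monetary-benefit strategy, splitting exact ties equally,
so probabilities sum to 1 at every WTP.

## Synthetic trials

The simulator draws subject-level PFS and OS times from known
distributions, couples them comonotonically through a shared uniform —
preserving both marginals exactly, which the parameter-recovery tests
require — and clips PFS ≤ OS per subject through any residual
crossing region (possible near t = 0 when shapes differ; grossly
inverted curve pairs are rejected at construction). Censoring combines
uniform staggered entry with administrative cutoff and an optional
uniform-dropout probability. The digitized-export step evaluates the
KM estimate on a grid and counts subjects at risk at requested times,
mimicking a figure digitizer. What the simulator does *not* emulate:
patient covariates, informative censoring, digitization bias beyond
optional uniform jitter, and reader error in the at-risk table — so
passing recovery tests demonstrate correctness of the reconstruction
machinery, not robustness to real-world digitization artifacts.

Default study conditions used by the tests and the acceptance script:
500 subjects per arm, 6-month enrolment window, 30-month cutoff, 10%
random censoring, 30 digitized points, at-risk readings every 3 months
— sizes typical of the trials this model class consumes. The recovery
study uses 20 seeded replicates per family; the full pipeline runs
both countries with a 1000-draw PSA.

## Known limitations

* Subsequent-therapy duration caps are approximated on the model clock
  (see above); tunnel states would remove the approximation at the
  cost of a much larger state space.
* Base-case curves and subgroup multipliers are illustrative; all
  headline ICERs computed on them are demonstrations of the machinery,
  not reproductions of the published point estimates, whose fitted
  inputs are not public.
* No vial rounding/wastage, indirect costs, inflation adjustment,
  imperfect test characteristics, EVPI, or correlated PSA.
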