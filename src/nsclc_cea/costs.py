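"""Per-cycle treatment cost schedules for each arm and country.

Covers drug acquisition under BSA/weight-based dosing, the 4-cycle
induction / maintenance split (pembrolizumab capped at 35 cycles), the
Chinese charity donation schedule for pembrolizumab (5 paid + 5 donated,
then alternating 3 + 3), adverse-event management, routine monitoring,
the one-time PD-L1 test, and post-progression subsequent therapy vs
supportive care.

All amounts are USD; Chinese prices were converted at a fixed
exchange rate before entry, so no conversion happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "DosingRule",
    "BodyMetrics",
    "EconomicInputs",
    "drug_cycle_cost",
    "payable_fraction_cn",
    "arm_cycle_cost",
    "arm_cost_vectors",
    "FIRST_LINE_DOSING",
]

Arm = Literal["chemo", "combo"]
ARMS = ("chemo", "combo")


@dataclass(frozen=True)
class DosingRule:
    """How a per-administration dose is computed.

    ``basis``: ``flat_mg`` (fixed mg), ``per_m2`` (mg per m² BSA),
    ``per_kg`` (mg per kg body weight) or ``fixed_dose`` (pre-computed
    total mg, e.g. a Calvert-formula carboplatin dose).
    """

    basis: Literal["flat_mg", "per_m2", "per_kg", "fixed_dose"]
    dose: float
    max_cycles: int | None = None

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be positive")

    def total_mg(self, body: "BodyMetrics") -> float:
        if self.basis in ("flat_mg", "fixed_dose"):
            return self.dose
        if self.basis == "per_m2":
            return self.dose * body.bsa
        return self.dose * body.weight


@dataclass(frozen=True)
class BodyMetrics:
    """Reference body size used for dose calculation."""

    bsa: float    # m²
    weight: float  # kg

    def __post_init__(self) -> None:
        if self.bsa <= 0 or self.weight <= 0:
            raise ValueError("body metrics must be positive")


#: First-line regimen dosing, administered every 3 weeks.  Carboplatin is
#: dosed by AUC 5 via the Calvert formula; with no renal function stated a
#: fixed 750 mg total dose (AUC 5 x (GFR 125 + 25)) is used, configurable
#: through EconomicInputs.carboplatin_dose_mg.
FIRST_LINE_DOSING: dict[str, DosingRule] = {
    "pembrolizumab": DosingRule("flat_mg", 200.0, max_cycles=35),
    "pemetrexed": DosingRule("per_m2", 500.0),
    "cisplatin": DosingRule("per_m2", 75.0),
    "carboplatin": DosingRule("fixed_dose", 750.0),
}

_DRUGS = ("pembrolizumab", "pemetrexed", "carboplatin", "cisplatin", "nivolumab", "docetaxel")


@dataclass
class EconomicInputs:
    """All country-specific prices, costs, utilities and proportions.

    ``ranges`` maps sensitivity-analysis parameter names to (low, high)
    bounds; names match the keys accepted by
    :func:`nsclc_cea.sensitivity.apply_overrides`.
    """

    country: str
    prices: dict[str, float]                       # USD per mg
    monitoring_cost: float                         # per on-treatment cycle
    pdl1_test_cost: float                          # one-time
    subsequent_cycle_costs: dict[str, float]       # per PD cycle, by drug
    supportive_care_cost: float                    # per PD cycle
    ae_costs: dict[str, float]                     # per managed event
    ae_incidence: dict[str, float]                 # grade >=3 incidence per patient
    utilities: dict[str, float]                    # PFS, PD
    prop_subsequent: dict[str, float]              # arm -> proportion treated post-PD
    prevalence: dict[str, float]                   # lt1, pd1to49, ge50
    discount_rate: float
    wtp: float
    exchange_rate_cny_per_usd: float
    body: BodyMetrics
    subsequent_mix: dict[str, dict[str, float]]    # arm -> drug -> share
    platinum_mix: dict[str, float] = field(
        default_factory=lambda: {"carboplatin": 0.5, "cisplatin": 0.5})
    carboplatin_dose_mg: float = 750.0
    induction_cycles: int = 4
    max_pembro_cycles: int = 35
    subsequent_max_cycles: dict[str, int | None] = field(
        default_factory=lambda: {"pembrolizumab": 35, "nivolumab": 35, "docetaxel": None})
    premedication_cost_per_cycle: float = 0.0
    cn_donation: bool = False
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, v in self.prices.items():
            if v < 0:
                raise ValueError(f"price of {name} is negative")
        for v in (self.monitoring_cost, self.pdl1_test_cost, self.supportive_care_cost,
                  self.premedication_cost_per_cycle):
            if v < 0:
                raise ValueError("costs must be non-negative")
        for st, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise ValueError(f"utility {st}={u} outside [0, 1]")
        for arm, p in self.prop_subsequent.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"subsequent-therapy proportion for {arm} outside [0, 1]")
        if abs(sum(self.prevalence.values()) - 1.0) > 0.005:
            raise ValueError("PD-L1 prevalence weights must sum to 1 (±0.005)")
        for arm, mix in self.subsequent_mix.items():
            if mix and abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"subsequent-therapy mix for {arm} must sum to 1")
        if abs(sum(self.platinum_mix.values()) - 1.0) > 1e-9:
            raise ValueError("platinum mix must sum to 1")

    def copy(self) -> "EconomicInputs":
        return replace(
            self,
            prices=dict(self.prices),
            subsequent_cycle_costs=dict(self.subsequent_cycle_costs),
            ae_costs=dict(self.ae_costs),
            ae_incidence=dict(self.ae_incidence),
            utilities=dict(self.utilities),
            prop_subsequent=dict(self.prop_subsequent),
            prevalence=dict(self.prevalence),
            subsequent_mix={a: dict(m) for a, m in self.subsequent_mix.items()},
            platinum_mix=dict(self.platinum_mix),
            subsequent_max_cycles=dict(self.subsequent_max_cycles),
            ranges=dict(self.ranges),
        )


def drug_cycle_cost(rule: DosingRule, body: BodyMetrics, unit_price: float) -> float:
    """Acquisition cost of one administration: total mg x USD/mg."""
    if unit_price < 0:
        raise ValueError("unit price must be non-negative")
    return rule.total_mg(body) * unit_price


def payable_fraction_cn(cycle_index: int) -> int:
    """Payable indicator under the Chinese pembrolizumab donation plan.

    1-based treatment cycles: patients pay cycles 1-5, receive donated
    drug cycles 6-10, then alternate 3 paid / 3 donated (11-13 paid,
    14-16 donated, ...) until treatment stops.
    """
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based and must be >= 1")
    if cycle_index <= 5:
        return 1
    if cycle_index <= 10:
        return 0
    return 1 if (cycle_index - 11) % 6 < 3 else 0


def _effective_price(inputs: EconomicInputs, drug: str,
                     scenario: Mapping[str, float] | None) -> float:
    mult = 1.0
    if scenario:
        mult = scenario.get(drug, 1.0)
    return inputs.prices[drug] * mult


def _check_scenario(scenario: Mapping[str, float] | None) -> None:
    if scenario:
        unknown = set(scenario) - set(_DRUGS)
        if unknown:
            raise ValueError(f"unknown drug key(s) in price scenario: {sorted(unknown)}")


def _first_line_pfs_cost(arm: str, cycle_index: int, inputs: EconomicInputs,
                         scenario: Mapping[str, float] | None) -> float:
    body = inputs.body
    cost = inputs.monitoring_cost + inputs.premedication_cost_per_cycle
    # pemetrexed continues every on-treatment cycle (induction + maintenance)
    cost += drug_cycle_cost(FIRST_LINE_DOSING["pemetrexed"], body,
                            _effective_price(inputs, "pemetrexed", scenario))
    if cycle_index <= inputs.induction_cycles:
        carb = DosingRule("fixed_dose", inputs.carboplatin_dose_mg)
        cost += inputs.platinum_mix.get("carboplatin", 0.0) * drug_cycle_cost(
            carb, body, _effective_price(inputs, "carboplatin", scenario))
        cost += inputs.platinum_mix.get("cisplatin", 0.0) * drug_cycle_cost(
            FIRST_LINE_DOSING["cisplatin"], body,
            _effective_price(inputs, "cisplatin", scenario))
        # grade >=3 AE management, incidence-weighted and spread over induction
        ae = sum(inputs.ae_incidence.get(k, 0.0) * c for k, c in inputs.ae_costs.items())
        cost += ae / inputs.induction_cycles
    if arm == "combo" and cycle_index <= inputs.max_pembro_cycles:
        pembro = drug_cycle_cost(FIRST_LINE_DOSING["pembrolizumab"], body,
                                 _effective_price(inputs, "pembrolizumab", scenario))
        if inputs.cn_donation:
            pembro *= payable_fraction_cn(cycle_index)
        cost += pembro
    return cost


def _pd_cost(arm: str, cycle_index: int, inputs: EconomicInputs,
             scenario: Mapping[str, float] | None) -> float:
    prop = inputs.prop_subsequent[arm]
    mix = inputs.subsequent_mix[arm]
    treated = 0.0
    for drug, share in mix.items():
        cap = inputs.subsequent_max_cycles.get(drug)
        if cap is not None and cycle_index > cap:
            treated += share * inputs.supportive_care_cost
            continue
        mult = scenario.get(drug, 1.0) if scenario else 1.0
        treated += share * inputs.subsequent_cycle_costs[drug] * mult
    return prop * treated + (1.0 - prop) * inputs.supportive_care_cost


def arm_cycle_cost(arm: str, cycle_index: int, state: str, inputs: EconomicInputs,
                   scenario: Mapping[str, float] | None = None) -> float:
    """Cost accrued by one patient in ``state`` during treatment cycle
    ``cycle_index`` (1-based) of the given arm.

    PFS cycles carry first-line drug acquisition (induction: platinum +
    pemetrexed (+ pembrolizumab in the combination arm); maintenance:
    pemetrexed (+ pembrolizumab up to the 35-cycle cap)), monitoring,
    and incidence-weighted adverse-event management during induction.
    PD cycles carry the subsequent-therapy / supportive-care mixture.
    Death costs nothing.  ``scenario`` maps drug names to price
    multipliers.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based and must be >= 1")
    _check_scenario(scenario)
    if state == "Death":
        return 0.0
    if state == "PFS":
        return _first_line_pfs_cost(arm, cycle_index, inputs, scenario)
    if state == "PD":
        return _pd_cost(arm, cycle_index, inputs, scenario)
    raise ValueError(f"unknown state {state!r}")


def arm_cost_vectors(arm: str, inputs: EconomicInputs, n_cycles: int,
                     scenario: Mapping[str, float] | None = None) -> dict[str, np.ndarray]:
    """Per-cycle cost vectors for PFS and PD over ``n_cycles`` model cycles.

    Model cycle k (0-based) corresponds to treatment cycle k+1.
    Vectorized equivalent of looping :func:`arm_cycle_cost`; the unit
    test asserts element-wise agreement.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    _check_scenario(scenario)
    cyc = np.arange(1, n_cycles + 1)
    body = inputs.body

    pfs = np.full(n_cycles, inputs.monitoring_cost + inputs.premedication_cost_per_cycle)
    pfs += drug_cycle_cost(FIRST_LINE_DOSING["pemetrexed"], body,
                           _effective_price(inputs, "pemetrexed", scenario))
    induction = cyc <= inputs.induction_cycles
    plat = (inputs.platinum_mix.get("carboplatin", 0.0)
            * inputs.carboplatin_dose_mg * _effective_price(inputs, "carboplatin", scenario)
            + inputs.platinum_mix.get("cisplatin", 0.0)
            * drug_cycle_cost(FIRST_LINE_DOSING["cisplatin"], body,
                              _effective_price(inputs, "cisplatin", scenario)))
    ae = sum(inputs.ae_incidence.get(k, 0.0) * c for k, c in inputs.ae_costs.items())
    pfs[induction] += plat + ae / inputs.induction_cycles
    if arm == "combo":
        pembro_unit = drug_cycle_cost(FIRST_LINE_DOSING["pembrolizumab"], body,
                                      _effective_price(inputs, "pembrolizumab", scenario))
        on_pembro = (cyc <= inputs.max_pembro_cycles).astype(float)
        if inputs.cn_donation:
            payable = np.array([payable_fraction_cn(int(c)) for c in cyc], dtype=float)
            on_pembro *= payable
        pfs += pembro_unit * on_pembro

    prop = inputs.prop_subsequent[arm]
    treated = np.zeros(n_cycles)
    for drug, share in inputs.subsequent_mix[arm].items():
        cap = inputs.subsequent_max_cycles.get(drug)
        mult = scenario.get(drug, 1.0) if scenario else 1.0
        per_cycle = np.full(n_cycles, inputs.subsequent_cycle_costs[drug] * mult)
        if cap is not None:
            per_cycle[cyc > cap] = inputs.supportive_care_cost
        treated += share * per_cycle
    pd = prop * treated + (1.0 - prop) * inputs.supportive_care_cost
    return {"PFS": pfs, "PD": np.asarray(pd, dtype=float)}
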