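"""Decision-tree strategies: treat-all arms and PD-L1 test-guided therapy.

Three strategy kinds are modelled:

* ``all_chemo`` — every patient receives platinum/pemetrexed chemotherapy;
* ``all_combo`` — every patient receives pembrolizumab + chemotherapy;
* ``test_guided`` — patients are PD-L1 tested once at entry and treated
  with the combination if their tumor proportion score clears the
  cutoff (1% or 50%), chemotherapy otherwise.

A test-guided strategy is a prevalence-weighted mixture of per-stratum
arm evaluations plus the one-time test cost; subgroup survival enters
through per-(arm, stratum) scale multipliers on the overall curves.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Mapping

from .costs import EconomicInputs, arm_cost_vectors
from .economics import StrategyResult
from .markov import DiscountSpec, accrue_outcomes, build_trace
from .survival import CYCLE_LENGTH_MONTHS, SurvivalDistribution

__all__ = ["CurveSet", "StrategySpec", "CEModel", "evaluate_arm",
           "evaluate_test_strategy", "STRATA", "combo_fraction"]

#: PD-L1 tumor proportion score strata: <1%, 1-49%, >=50%.
STRATA = ("lt1", "pd1to49", "ge50")


@dataclass(frozen=True)
class CurveSet:
    """The OS/PFS curve pair that drives one arm's cohort trace."""

    os: SurvivalDistribution
    pfs: SurvivalDistribution

    def scaled(self, time_multiplier: float) -> "CurveSet":
        """Accelerated-failure-time rescaling: multiply both scales."""
        if time_multiplier <= 0:
            raise ValueError("time multiplier must be positive")
        return CurveSet(
            os=replace(self.os, scale=self.os.scale * time_multiplier),
            pfs=replace(self.pfs, scale=self.pfs.scale * time_multiplier),
        )


@dataclass(frozen=True)
class StrategySpec:
    name: str
    kind: Literal["all_chemo", "all_combo", "test_guided"]
    cutoff: Literal["1pct", "50pct"] | None = None

    def __post_init__(self) -> None:
        if self.kind == "test_guided" and self.cutoff not in ("1pct", "50pct"):
            raise ValueError("test_guided strategies need a cutoff of '1pct' or '50pct'")


def evaluate_arm(arm: str, curves: CurveSet, inputs: EconomicInputs,
                 scenario: Mapping[str, float] | None = None,
                 horizon_years: float = 20.0,
                 cycle_length: float = CYCLE_LENGTH_MONTHS,
                 half_cycle_correction: bool = False,
                 name: str | None = None) -> StrategyResult:
    """Discounted mean cost and QALYs of treating everyone with one arm."""
    trace = build_trace(curves.os, curves.pfs, horizon_years, cycle_length)
    cost_vectors = arm_cost_vectors(arm, inputs, trace.n_cycles, scenario)
    spec = DiscountSpec(inputs.discount_rate)
    cost, qaly = accrue_outcomes(trace, inputs.utilities, cost_vectors, spec,
                                 half_cycle_correction)
    return StrategyResult(name or arm, cost, qaly)


def combo_fraction(cutoff: str, prevalence: Mapping[str, float]) -> float:
    """Fraction of tested patients routed to the combination arm."""
    if cutoff == "1pct":
        return prevalence["pd1to49"] + prevalence["ge50"]
    if cutoff == "50pct":
        return prevalence["ge50"]
    raise ValueError(f"unknown cutoff {cutoff!r}")


def evaluate_test_strategy(cutoff: str, arm_curves: Mapping[str, CurveSet],
                           inputs: EconomicInputs,
                           subgroup_multipliers: Mapping[str, Mapping[str, float]] | None = None,
                           scenario: Mapping[str, float] | None = None,
                           horizon_years: float = 20.0,
                           cycle_length: float = CYCLE_LENGTH_MONTHS,
                           half_cycle_correction: bool = False,
                           name: str | None = None) -> StrategyResult:
    """Evaluate the PD-L1 test-guided strategy at a given cutoff.

    Each stratum is run through the arm it is routed to (stratum-specific
    curves when multipliers are supplied, the overall arm curves
    otherwise — the test is treated as perfectly accurate), and the
    results are mixed by prevalence.  Every tested patient pays the
    PD-L1 test once at model entry (undiscounted, t = 0).
    """
    prevalence = inputs.prevalence
    if abs(sum(prevalence[s] for s in STRATA) - 1.0) > 0.005:
        raise ValueError("prevalence weights must sum to 1")
    cost = inputs.pdl1_test_cost
    qaly = 0.0
    for stratum in STRATA:
        if cutoff == "1pct":
            arm = "chemo" if stratum == "lt1" else "combo"
        else:
            arm = "combo" if stratum == "ge50" else "chemo"
        curves = arm_curves[arm]
        if subgroup_multipliers and arm in subgroup_multipliers:
            mult = subgroup_multipliers[arm].get(stratum, 1.0)
            if mult != 1.0:
                curves = curves.scaled(mult)
        res = evaluate_arm(arm, curves, inputs, scenario, horizon_years,
                           cycle_length, half_cycle_correction)
        w = prevalence[stratum]
        cost += w * res.cost
        qaly += w * res.qaly
    return StrategyResult(name or f"test_{cutoff}", cost, qaly)


@dataclass
class CEModel:
    """A fully specified cost-effectiveness model: inputs, curves, strategies.

    This is the object the sensitivity analyses re-evaluate under
    parameter overrides; ``evaluate_all`` returns one
    :class:`StrategyResult` per declared strategy.
    """

    inputs: EconomicInputs
    arm_curves: dict[str, CurveSet]
    strategies: list[StrategySpec]
    subgroup_multipliers: dict[str, dict[str, float]] | None = None
    scenario: dict[str, float] | None = None
    horizon_years: float = 20.0
    cycle_length: float = CYCLE_LENGTH_MONTHS
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError("strategy names must be unique")

    def evaluate(self, spec: StrategySpec) -> StrategyResult:
        if spec.kind == "all_chemo":
            return evaluate_arm("chemo", self.arm_curves["chemo"], self.inputs,
                                self.scenario, self.horizon_years, self.cycle_length,
                                self.half_cycle_correction, name=spec.name)
        if spec.kind == "all_combo":
            return evaluate_arm("combo", self.arm_curves["combo"], self.inputs,
                                self.scenario, self.horizon_years, self.cycle_length,
                                self.half_cycle_correction, name=spec.name)
        return evaluate_test_strategy(spec.cutoff, self.arm_curves, self.inputs,
                                      self.subgroup_multipliers, self.scenario,
                                      self.horizon_years, self.cycle_length,
                                      self.half_cycle_correction, name=spec.name)

    def evaluate_all(self) -> dict[str, StrategyResult]:
        return {s.name: self.evaluate(s) for s in self.strategies}

    def copy(self) -> "CEModel":
        return CEModel(
            inputs=self.inputs.copy(),
            arm_curves=dict(self.arm_curves),
            strategies=list(self.strategies),
            subgroup_multipliers=(None if self.subgroup_multipliers is None else
                                  {a: dict(m) for a, m in self.subgroup_multipliers.items()}),
            scenario=None if self.scenario is None else dict(self.scenario),
            horizon_years=self.horizon_years,
            cycle_length=self.cycle_length,
            half_cycle_correction=self.half_cycle_correction,
        )
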