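"""Price-reduction scenario analysis.

A scenario is a set of multiplicative price changes keyed by drug
(e.g. pembrolizumab at 0.85 or 0.60 of list price in the US, 0.50 in
China).  Multipliers touch only the cost side — QALYs are invariant
across price scenarios — and in China the charity donation schedule
still applies on top of the reduced price unless explicitly disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .economics import incremental_frontier, pairwise_table
from .strategies import CEModel

__all__ = ["Scenario", "run_scenarios"]


@dataclass(frozen=True)
class Scenario:
    """Named set of drug price multipliers (1.0 = list price)."""

    name: str
    multipliers: dict[str, float] = field(default_factory=dict)
    disable_cn_donation: bool = False

    def __post_init__(self) -> None:
        for drug, m in self.multipliers.items():
            if m <= 0:
                raise ValueError(f"{self.name}: multiplier for {drug} must be positive")


def run_scenarios(model: CEModel, scenarios: list[Scenario],
                  reference: str = "all_chemo",
                  also_vs: str | None = "all_combo") -> dict[str, pd.DataFrame]:
    """Evaluate the full strategy set under each scenario.

    A base scenario (all multipliers 1) is always included as control.
    Each value is a publication-style incremental table; frontier
    classification is available via
    :func:`nsclc_cea.economics.incremental_frontier` on the same
    results.
    """
    all_scenarios = [Scenario("base")] + list(scenarios)
    out: dict[str, pd.DataFrame] = {}
    for sc in all_scenarios:
        m = model.copy()
        merged = dict(m.scenario or {})
        for drug, mult in sc.multipliers.items():
            merged[drug] = merged.get(drug, 1.0) * mult
        m.scenario = merged or None
        if sc.disable_cn_donation:
            m.inputs.cn_donation = False
        results = list(m.evaluate_all().values())
        table = pairwise_table(results, reference=reference,
                               also_vs=also_vs if also_vs in {r.name for r in results} else None)
        frontier = pd.DataFrame([vars(r) for r in incremental_frontier(results)])
        table["scenario"] = sc.name
        out[sc.name] = table
        out[f"{sc.name}__frontier"] = frontier
    return out
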