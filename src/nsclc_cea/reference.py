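"""Published reference values for validation.

``published_strategy_means`` loads the mean discounted cost and QALYs
per strategy reported in the published US/China evaluation of
first-line pembrolizumab plus chemotherapy, for the base cases and the
pembrolizumab price-reduction scenarios.  Feeding these means through
the incremental-analysis operations must reproduce the published
incremental costs, incremental QALYs, ICERs and dominance labels —
a pure-arithmetic validation layer that does not depend on the
unavailable fitted survival parameters.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .economics import StrategyResult

__all__ = ["published_strategy_means", "strategy_results"]


def published_strategy_means() -> pd.DataFrame:
    """Long-format table: country, scenario, strategy, cost, qaly."""
    ref = resources.files("nsclc_cea").joinpath("data", "published_strategy_means.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def strategy_results(country: str, scenario: str = "base") -> list[StrategyResult]:
    """The published strategy means as :class:`StrategyResult` objects."""
    df = published_strategy_means()
    sel = df[(df["country"] == country) & (df["scenario"] == scenario)]
    if sel.empty:
        raise KeyError(f"no published means for {country!r} / {scenario!r}")
    return [StrategyResult(r.strategy, float(r.cost), float(r.qaly))
            for r in sel.itertuples()]
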