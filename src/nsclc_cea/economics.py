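"""Incremental cost-effectiveness: ICERs, dominance, the efficiency frontier.

Terminology: strategy B *strictly dominates* A when B costs no more and
yields no fewer QALYs, with at least one strict inequality.  A is
*extendedly (weakly) dominated* when a linear combination of two other
strategies dominates it — detected, as usual, by an ICER that exceeds
that of the next more effective frontier option.  Frontier ICERs are
strictly increasing with effectiveness by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "StrategyResult",
    "IcerOutcome",
    "IncrementalRow",
    "icer",
    "net_monetary_benefit",
    "incremental_frontier",
    "pairwise_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StrategyResult:
    """Discounted mean cost (USD) and mean QALYs of one strategy."""

    name: str
    cost: float
    qaly: float

    def __post_init__(self) -> None:
        if self.cost < 0 or self.qaly < 0:
            raise ValueError("cost and QALY must be non-negative")


@dataclass(frozen=True)
class IcerOutcome:
    """Either a numeric ICER (USD/QALY) or a dominance label."""

    value: float | None
    label: str  # "icer", "alternative dominates", "alternative dominated", "equivalent", ...
    delta_cost: float
    delta_qaly: float

    @property
    def is_numeric(self) -> bool:
        return self.value is not None


def icer(reference: StrategyResult, alternative: StrategyResult) -> IcerOutcome:
    """Incremental cost-effectiveness ratio of alternative vs reference.

    Returns a numeric ratio only when it is interpretable; sign patterns
    that indicate dominance come back as labels instead of a division.
    """
    dc = alternative.cost - reference.cost
    dq = alternative.qaly - reference.qaly
    if dq == 0.0 and dc == 0.0:
        return IcerOutcome(None, "equivalent", dc, dq)
    if dq == 0.0:
        label = "alternative dominated" if dc > 0 else "alternative dominates"
        return IcerOutcome(None, label, dc, dq)
    if dq > 0 and dc <= 0:
        return IcerOutcome(None, "alternative dominates", dc, dq)
    if dq < 0 and dc >= 0:
        return IcerOutcome(None, "alternative dominated", dc, dq)
    # remaining quadrants (NE and SW) have a meaningful ratio
    return IcerOutcome(dc / dq, "icer", dc, dq)


def net_monetary_benefit(result: StrategyResult, wtp: float) -> float:
    """NMB = WTP x QALY - cost, the decision statistic behind CEACs."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * result.qaly - result.cost


@dataclass
class IncrementalRow:
    """One line of an incremental analysis table."""

    strategy: str
    cost: float
    qaly: float
    comparator: str | None
    delta_cost: float | None
    delta_qaly: float | None
    icer: float | None
    status: str  # "frontier", "dominated", "extendedly_dominated", "reference"


def _dedupe(results: Sequence[StrategyResult]) -> list[StrategyResult]:
    seen: dict[tuple[float, float], str] = {}
    out = []
    for r in results:
        key = (r.cost, r.qaly)
        if key in seen:
            logger.info("strategy %s duplicates %s; keeping first", r.name, seen[key])
            continue
        seen[key] = r.name
        out.append(r)
    return out


def incremental_frontier(results: Sequence[StrategyResult]) -> list[IncrementalRow]:
    """Classify strategies and compute sequential ICERs along the frontier.

    Strategies are sorted by cost; strictly dominated options are
    flagged, then extendedly dominated ones are removed iteratively
    (an option whose ICER against the previous frontier member is at
    least that of the next member is excluded; at exactly equal
    sequential ICERs — collinear strategies — the middle one is kept).
    Rows come back in cost order with the cheapest frontier member as
    reference.
    """
    if len(results) < 2:
        raise ValueError("frontier analysis needs at least two strategies")
    results = _dedupe(results)
    ordered = sorted(results, key=lambda r: (r.cost, -r.qaly))

    dominated = set()
    for r in ordered:
        for other in ordered:
            if other.name == r.name:
                continue
            if (other.cost <= r.cost and other.qaly >= r.qaly
                    and (other.cost < r.cost or other.qaly > r.qaly)):
                dominated.add(r.name)
                break

    frontier = [r for r in ordered if r.name not in dominated]
    ext_dominated: set[str] = set()
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            prev, cur, nxt = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_in = (cur.cost - prev.cost) / (cur.qaly - prev.qaly)
            icer_out = (nxt.cost - cur.cost) / (nxt.qaly - cur.qaly)
            if icer_in > icer_out:  # strictly greater: collinear middle kept
                ext_dominated.add(cur.name)
                frontier = frontier[:i] + frontier[i + 1:]
                changed = True
                break

    rows: list[IncrementalRow] = []
    prev: StrategyResult | None = None
    for r in ordered:
        if r.name in dominated:
            rows.append(IncrementalRow(r.name, r.cost, r.qaly, None, None, None, None,
                                       "dominated"))
        elif r.name in ext_dominated:
            rows.append(IncrementalRow(r.name, r.cost, r.qaly, None, None, None, None,
                                       "extendedly_dominated"))
        elif prev is None:
            rows.append(IncrementalRow(r.name, r.cost, r.qaly, None, None, None, None,
                                       "reference"))
            prev = r
        else:
            out = icer(prev, r)
            rows.append(IncrementalRow(r.name, r.cost, r.qaly, prev.name,
                                       out.delta_cost, out.delta_qaly, out.value,
                                       "frontier"))
            prev = r
    return rows


def pairwise_table(results: Sequence[StrategyResult], reference: str,
                   also_vs: str | None = None) -> pd.DataFrame:
    """Publication-style incremental table.

    Every strategy is compared against ``reference`` (typically the
    chemotherapy-for-all arm); strategies other than ``also_vs`` are
    additionally compared against ``also_vs`` (typically the treat-all
    combination arm), which is how biomarker-test strategies are usually
    reported.  Dominance sign patterns appear as labels in the ICER
    column.
    """
    by_name = {r.name: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference strategy {reference!r} not in results")
    rows = []
    ref = by_name[reference]
    rows.append({"strategy": ref.name, "cost": ref.cost, "qaly": ref.qaly,
                 "comparator": None, "delta_cost": None, "delta_qaly": None,
                 "icer": None})

    def fmt(out: IcerOutcome):
        # publication convention: the label describes the comparator's fate,
        # so a row whose strategy beats its comparator on both axes prints
        # "dominated" (the comparator is dominated)
        if out.is_numeric:
            return out.value
        if out.label == "alternative dominates":
            return "dominated"
        if out.label == "alternative dominated":
            return "dominated by comparator"
        return out.label

    for r in results:
        if r.name == reference:
            continue
        out = icer(ref, r)
        rows.append({"strategy": r.name, "cost": r.cost, "qaly": r.qaly,
                     "comparator": reference, "delta_cost": out.delta_cost,
                     "delta_qaly": out.delta_qaly, "icer": fmt(out)})
        if also_vs and r.name != also_vs and also_vs in by_name:
            out2 = icer(by_name[also_vs], r)
            rows.append({"strategy": r.name, "cost": r.cost, "qaly": r.qaly,
                         "comparator": also_vs, "delta_cost": out2.delta_cost,
                         "delta_qaly": out2.delta_qaly, "icer": fmt(out2)})
    return pd.DataFrame(rows)
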