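"""Incremental analysis: ICERs, dominance, frontier, net monetary benefit."""

import numpy as np
import pytest

import nsclc_cea as nc
from nsclc_cea import StrategyResult, icer, incremental_frontier, net_monetary_benefit
from nsclc_cea.economics import pairwise_table


def test_icer_arithmetic_on_published_increments():
    chemo = StrategyResult("chemo", 153551, 0.88)
    combo = StrategyResult("combo", 256421, 1.66)
    out = icer(chemo, combo)
    assert out.delta_cost == pytest.approx(102870)
    assert out.delta_qaly == pytest.approx(0.78)
    assert out.value == pytest.approx(102870 / 0.78)


def test_icer_labels():
    a = StrategyResult("a", 100.0, 1.0)
    assert icer(a, StrategyResult("b", 100.0, 1.0)).label == "equivalent"
    assert icer(a, StrategyResult("c", 80.0, 1.2)).label == "alternative dominates"
    assert icer(a, StrategyResult("d", 120.0, 0.9)).label == "alternative dominated"
    assert icer(a, StrategyResult("e", 120.0, 1.0)).label == "alternative dominated"
    dom = icer(StrategyResult("combo", 256421, 1.66), StrategyResult("test", 234795, 1.93))
    assert dom.label == "alternative dominates"
    assert dom.delta_cost == pytest.approx(-21626)
    assert dom.delta_qaly == pytest.approx(0.27)


@pytest.mark.parametrize("cost,qaly,wtp,expected", [
    (0.0, 1.0, 100_000, 100_000.0),
    (153551, 0.88, 100_000, 0.88 * 100_000 - 153551),
    (500.0, 0.3, 0.0, -500.0),
])
def test_net_monetary_benefit(cost, qaly, wtp, expected):
    assert net_monetary_benefit(StrategyResult("s", cost, qaly), wtp) == \
        pytest.approx(expected)


def test_equal_qaly_cheaper_on_frontier():
    rows = incremental_frontier([StrategyResult("cheap", 100, 1.0),
                                 StrategyResult("dear", 200, 1.0)])
    status = {r.strategy: r.status for r in rows}
    assert status == {"cheap": "reference", "dear": "dominated"}


def test_collinear_middle_strategy_retained():
    rows = incremental_frontier([StrategyResult("a", 0, 0.0),
                                 StrategyResult("b", 100, 1.0),
                                 StrategyResult("c", 200, 2.0)])
    assert all(r.status in ("reference", "frontier") for r in rows)


def test_extended_dominance_detected():
    # b's ICER vs a (1000) exceeds c's ICER vs b (500): b extendedly dominated
    rows = incremental_frontier([StrategyResult("a", 0, 0.0),
                                 StrategyResult("b", 1000, 1.0),
                                 StrategyResult("c", 1500, 2.0)])
    status = {r.strategy: r.status for r in rows}
    assert status["b"] == "extendedly_dominated"
    assert status["c"] == "frontier"


def test_frontier_icers_strictly_increase():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = rng.integers(3, 8)
        results = [StrategyResult(f"s{i}", float(c), float(q))
                   for i, (c, q) in enumerate(zip(rng.uniform(0, 1e5, n),
                                                  rng.uniform(0, 3, n)))]
        rows = incremental_frontier(results)
        icers = [r.icer for r in rows if r.icer is not None]
        assert all(b > a for a, b in zip(icers, icers[1:]))


def test_max_nmb_strategy_always_on_frontier():
    """Brute-force oracle: at any WTP the NMB-maximal strategy must not
    be (extendedly) dominated."""
    rng = np.random.default_rng(1)
    for _ in range(30):
        n = rng.integers(3, 8)
        results = [StrategyResult(f"s{i}", float(c), float(q))
                   for i, (c, q) in enumerate(zip(rng.uniform(0, 1e5, n),
                                                  rng.uniform(0, 3, n)))]
        rows = {r.strategy: r.status for r in incremental_frontier(results)}
        for wtp in (0.0, 2e4, 5e4, 1e5, 5e5):
            nmb = [net_monetary_benefit(r, wtp) for r in results]
            best = results[int(np.argmax(nmb))]
            assert rows[best.name] in ("reference", "frontier")


def test_duplicate_strategies_keep_first():
    rows = incremental_frontier([StrategyResult("a", 100, 1.0),
                                 StrategyResult("a_copy", 100, 1.0),
                                 StrategyResult("b", 200, 2.0)])
    names = {r.strategy for r in rows}
    assert "a_copy" not in names


@pytest.mark.parametrize("country,scenario,expected", [
    # (strategy, comparator) -> (delta_cost, delta_qaly, icer-or-label)
    ("US", "base", {
        ("all_combo", "all_chemo"): (102870, 0.78, "icer"),
        ("test_1pct", "all_chemo"): (81244, 1.05, "icer"),
        ("test_1pct", "all_combo"): (-21626, 0.27, "dominated"),
        ("test_50pct", "all_chemo"): (41250, 0.92, "icer"),
        ("test_50pct", "all_combo"): (-61620, 0.14, "dominated"),
    }),
    ("CN", "base", {
        ("all_combo", "all_chemo"): (54565, 0.59, "icer"),
        ("test_1pct", "all_chemo"): (42746, 0.75, "icer"),
        ("test_1pct", "all_combo"): (-11820, 0.16, "dominated"),
        ("test_50pct", "all_chemo"): (22009, 0.64, "icer"),
        ("test_50pct", "all_combo"): (-32556, 0.05, "dominated"),
    }),
    ("US", "pembro_minus_15", {("all_combo", "all_chemo"): (91748, 0.78, "icer")}),
    ("US", "pembro_minus_40", {("all_combo", "all_chemo"): (73211, 0.78, "icer")}),
    ("CN", "pembro_minus_50", {
        ("all_combo", "all_chemo"): (34992, 0.59, "icer"),
        ("test_1pct", "all_chemo"): (27267, 0.75, "icer"),
        ("test_1pct", "all_combo"): (-7725, 0.16, "dominated"),
        ("test_50pct", "all_chemo"): (14070, 0.64, "icer"),
        ("test_50pct", "all_combo"): (-20923, 0.05, "dominated"),
    }),
])
def test_published_incremental_tables_reproduced(country, scenario, expected):
    """Feeding the published strategy means through the pairwise analysis
    reproduces every published increment and dominance label.  Increments
    on QALYs are checked to the table's printed precision (0.01, allowing
    for the rounding of the published means themselves)."""
    results = nc.strategy_results(country, scenario)
    table = pairwise_table(results, reference="all_chemo", also_vs="all_combo")
    for (strategy, comparator), (dc, dq, kind) in expected.items():
        row = table[(table["strategy"] == strategy) &
                    (table["comparator"] == comparator)].iloc[0]
        assert row["delta_cost"] == pytest.approx(dc, abs=1.5)
        assert row["delta_qaly"] == pytest.approx(dq, abs=0.011)
        if kind == "dominated":
            assert row["icer"] == "dominated"
        else:
            assert row["icer"] == pytest.approx(
                row["delta_cost"] / row["delta_qaly"], rel=1e-9)


def test_published_dominance_structure_on_frontier():
    """In the published base cases the treat-all combination strategy is
    strictly dominated (the 1% test strategy is cheaper and more effective)."""
    for country in ("US", "CN"):
        rows = incremental_frontier(nc.strategy_results(country, "base"))
        status = {r.strategy: r.status for r in rows}
        assert status["all_combo"] == "dominated"
        assert status["all_chemo"] == "reference"


def test_negative_cost_or_qaly_rejected():
    with pytest.raises(ValueError):
        StrategyResult("bad", -1.0, 0.5)
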