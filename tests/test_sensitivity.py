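"""Deterministic and probabilistic sensitivity analysis, CEAC."""

import numpy as np
import pandas as pd
import pytest

import nsclc_cea as nc
from nsclc_cea.sensitivity import (ParamSpec, PsaResult, apply_overrides, ceac,
                                   default_param_specs, fit_moment_distribution,
                                   make_pair_evaluator, one_way_dsa, run_psa,
                                   sample_parameter)


def test_moment_matching_gamma_monitoring_cost():
    """cost mean 732, range (586, 878): sd = 74.49, shape = 96.56, scale = 7.58."""
    spec = ParamSpec("monitoring_cost", 732.0, 586.0, 878.0, "cost")
    kind, shape, scale = fit_moment_distribution(spec)
    assert kind == "gamma"
    assert shape == pytest.approx(96.567, abs=0.05)
    assert scale == pytest.approx(7.580, abs=0.005)
    assert shape * scale == pytest.approx(732.0)


def test_moment_matching_symmetric_beta_is_symmetric():
    spec = ParamSpec("u", 0.5, 0.3, 0.7, "utility")
    kind, a, b = fit_moment_distribution(spec)
    assert kind == "beta" and a == pytest.approx(b)


def test_degenerate_range_is_point_mass():
    spec = ParamSpec("u", 0.5, 0.5, 0.5, "utility")
    assert fit_moment_distribution(spec) == ("point", 0.5)
    draws = sample_parameter(spec, np.random.default_rng(0), 100)
    assert np.all(draws == 0.5)


def test_infeasible_beta_variance_clipped():
    spec = ParamSpec("p", 0.01, 0.0, 1.0, "probability")
    kind, a, b = fit_moment_distribution(spec)
    assert kind == "beta" and a > 0 and b > 0


def test_sampled_means_match_specs(us_model):
    specs = default_param_specs(us_model)
    rng = np.random.default_rng(123)
    n = 1000
    for spec in specs:
        draws = sample_parameter(spec, rng, n)
        sd = (spec.high - spec.low) / 3.92
        if sd == 0:
            continue
        se = sd / np.sqrt(n)
        assert abs(draws.mean() - spec.base) < 3.5 * se + 1e-12, spec.name


def test_apply_overrides_round_trip(us_model):
    m = apply_overrides(us_model, {"price_pembrolizumab": 10.0, "utility_pd": 0.3,
                                   "curve_combo_os_scale": 30.0})
    assert m.inputs.prices["pembrolizumab"] == 10.0
    assert m.inputs.utilities["PD"] == 0.3
    assert m.arm_curves["combo"].os.scale == 30.0
    # original untouched
    assert us_model.inputs.prices["pembrolizumab"] == pytest.approx(48.987)


def test_prevalence_overrides_renormalized(us_model):
    m = apply_overrides(us_model, {"prev_ge50": 0.6})
    assert sum(m.inputs.prevalence.values()) == pytest.approx(1.0)


def test_dsa_base_values_reproduce_base_case(us_model):
    """Setting any parameter to its base value must return the base ICER
    bit-identically."""
    evaluate = make_pair_evaluator(us_model, "all_combo", "all_chemo")
    base = evaluate({})
    for spec in default_param_specs(us_model)[:8]:
        out = evaluate({spec.name: spec.base})
        assert out.value == base.value


def test_dsa_zero_width_parameter_gives_zero_bar(us_model):
    evaluate = make_pair_evaluator(us_model, "all_combo", "all_chemo")
    fixed = ParamSpec("monitoring_cost", 732.0, 732.0, 732.0, "cost")
    table = one_way_dsa(evaluate, [fixed])
    assert table["width"].iloc[0] == pytest.approx(0.0)


def test_icer_monotone_in_pd_utility(us_model):
    """The combination becomes more cost-effective as PD utility rises."""
    evaluate = make_pair_evaluator(us_model, "all_combo", "all_chemo")
    icers = [evaluate({"utility_pd": u}).value for u in (0.2, 0.35, 0.47, 0.6, 0.75)]
    assert all(b < a for a, b in zip(icers, icers[1:]))


def test_icer_increases_with_pembrolizumab_price(us_model):
    evaluate = make_pair_evaluator(us_model, "all_combo", "all_chemo")
    lo = evaluate({"price_pembrolizumab": 39.2}).value
    hi = evaluate({"price_pembrolizumab": 58.8}).value
    assert lo < hi


def test_dsa_sorted_by_width_and_failures_flagged(us_model):
    evaluate = make_pair_evaluator(us_model, "all_combo", "all_chemo")
    specs = [ParamSpec("utility_pd", 0.47, 0.184, 0.773, "utility"),
             ParamSpec("monitoring_cost", 732.0, 586.0, 878.0, "cost")]
    table = one_way_dsa(evaluate, specs)
    widths = table["width"].to_numpy()
    assert np.all(np.diff(widths[~np.isnan(widths)]) <= 0)
    assert table.iloc[0]["parameter"] == "utility_pd"  # utilities dominate


def _tiny_evaluator(model):
    def evaluate(overrides):
        return apply_overrides(model, overrides).evaluate_all()
    return evaluate


def test_psa_reproducible_from_seed(us_model):
    specs = default_param_specs(us_model)[:6]
    ev = _tiny_evaluator(us_model)
    a = run_psa(ev, specs, n=5, seed=42)
    b = run_psa(ev, specs, n=5, seed=42)
    pd.testing.assert_frame_equal(a.results, b.results)
    pd.testing.assert_frame_equal(a.draws, b.draws)


def test_psa_degenerate_distributions_reproduce_base_case(us_model):
    base = us_model.evaluate_all()
    specs = [ParamSpec("monitoring_cost", 732.0, 732.0, 732.0, "cost"),
             ParamSpec("utility_pd", 0.47, 0.47, 0.47, "utility")]
    psa = run_psa(_tiny_evaluator(us_model), specs, n=4, seed=0)
    for _, row in psa.results.iterrows():
        assert row["cost"] == pytest.approx(base[row["strategy"]].cost)
        assert row["qaly"] == pytest.approx(base[row["strategy"]].qaly)


def test_ceac_rows_sum_to_one(us_model):
    specs = default_param_specs(us_model)
    psa = run_psa(_tiny_evaluator(us_model), specs, n=40, seed=7)
    curves = ceac(psa, [0.0, 27_351.0, 100_000.0, 200_000.0])
    assert np.allclose(curves.sum(axis=1), 1.0, atol=1e-12)
    assert np.all((curves.to_numpy() >= 0) & (curves.to_numpy() <= 1))


def test_ceac_direct_count_oracle():
    """Constructed 2-strategy PSA in which A wins exactly 634/1000 draws."""
    n = 1000
    wtp = 50_000.0
    rows = []
    for i in range(n):
        # A wins iff its NMB is higher; arrange by cost sign
        a_cost = 0.0 if i < 634 else 2e4
        rows.append({"draw": i, "strategy": "A", "cost": a_cost, "qaly": 1.0})
        rows.append({"draw": i, "strategy": "B", "cost": 1e4, "qaly": 1.0})
    psa = PsaResult(results=pd.DataFrame(rows), draws=pd.DataFrame(), n_failed=0, seed=0)
    curves = ceac(psa, [wtp])
    assert curves.loc[wtp, "A"] == pytest.approx(0.634)
    assert curves.loc[wtp, "B"] == pytest.approx(0.366)


def test_ceac_single_strategy_probability_one():
    rows = [{"draw": i, "strategy": "only", "cost": 100.0, "qaly": 1.0} for i in range(8)]
    psa = PsaResult(results=pd.DataFrame(rows), draws=pd.DataFrame(), n_failed=0, seed=0)
    curves = ceac(psa, [0.0, 1e5])
    assert np.all(curves["only"].to_numpy() == 1.0)


def test_ceac_dominant_strategy_everywhere():
    rows = []
    for i in range(10):
        rows.append({"draw": i, "strategy": "win", "cost": 50.0, "qaly": 2.0})
        rows.append({"draw": i, "strategy": "lose", "cost": 100.0, "qaly": 1.0})
    psa = PsaResult(results=pd.DataFrame(rows), draws=pd.DataFrame(), n_failed=0, seed=0)
    curves = ceac(psa, [0.0, 5e4, 2e5])
    assert np.all(curves["win"].to_numpy() == 1.0)
    assert np.all(curves["lose"].to_numpy() == 0.0)


def test_ceac_ties_split_equally():
    rows = []
    for i in range(4):
        rows.append({"draw": i, "strategy": "x", "cost": 100.0, "qaly": 1.0})
        rows.append({"draw": i, "strategy": "y", "cost": 100.0, "qaly": 1.0})
    psa = PsaResult(results=pd.DataFrame(rows), draws=pd.DataFrame(), n_failed=0, seed=0)
    curves = ceac(psa, [1e5])
    assert curves.iloc[0]["x"] == pytest.approx(0.5)
    assert curves.iloc[0]["y"] == pytest.approx(0.5)


def test_param_spec_validation():
    with pytest.raises(ValueError):
        ParamSpec("bad", 1.0, 2.0, 3.0, "cost")       # base below low
    with pytest.raises(ValueError):
        ParamSpec("bad", 0.5, 0.2, 1.4, "utility")    # above 1
    with pytest.raises(ValueError):
        ParamSpec("bad", 1.0, 0.5, 2.0, "weird")      # unknown class
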