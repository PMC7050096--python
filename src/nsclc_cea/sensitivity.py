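"""Deterministic and probabilistic sensitivity analysis.

One-way DSA sweeps each parameter to its low/high bound with everything
else held at base, producing tornado-diagram entries ordered by impact
on the ICER.  PSA draws all parameters jointly — beta distributions for
probabilities/utilities/proportions, gamma for costs/prices, lognormal
for survival-curve parameters — with hyperparameters moment-matched to
the base value and range (the range is read as a 95% interval, so
sd = (high - low) / 3.92).  Results feed cost-effectiveness
acceptability curves: at each willingness-to-pay, a strategy's
probability of being cost-effective is the fraction of draws in which
it attains the maximal net monetary benefit (ties split equally).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .economics import IcerOutcome, StrategyResult, icer
from .strategies import CEModel, STRATA

__all__ = [
    "ParamSpec",
    "fit_moment_distribution",
    "sample_parameter",
    "apply_overrides",
    "default_param_specs",
    "one_way_dsa",
    "run_psa",
    "PsaResult",
    "ceac",
]

logger = logging.getLogger(__name__)

_BOUNDED_CLASSES = ("probability", "utility", "proportion")
_POSITIVE_CLASSES = ("cost", "price")


@dataclass(frozen=True)
class ParamSpec:
    """One sensitivity-analysis parameter: base value and range."""

    name: str
    base: float
    low: float
    high: float
    klass: str  # probability | utility | proportion | cost | price | curve

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.klass in _BOUNDED_CLASSES:
            if not (0.0 <= self.low and self.high <= 1.0):
                raise ValueError(f"{self.name}: {self.klass} bounds must lie in [0, 1]")
        elif self.klass in _POSITIVE_CLASSES + ("curve",):
            if self.low < 0:
                raise ValueError(f"{self.name}: {self.klass} must be non-negative")
        else:
            raise ValueError(f"{self.name}: unknown parameter class {self.klass!r}")


def fit_moment_distribution(spec: ParamSpec) -> tuple:
    """Moment-matched sampling distribution for one parameter.

    Returns ``("point", base)`` for degenerate ranges,
    ``("beta", alpha, beta)`` for bounded classes,
    ``("gamma", shape, scale)`` for cost/price classes, and
    ``("lognormal", mu, sigma)`` for survival-curve parameters.
    A beta variance that exceeds the feasible m(1-m) bound is clipped
    (with a log message) to 90% of the bound.
    """
    m = spec.base
    sd = (spec.high - spec.low) / (2 * 1.96)
    if sd == 0.0 or (spec.klass in _POSITIVE_CLASSES + ("curve",) and m == 0.0):
        return ("point", m)
    v = sd * sd
    if spec.klass in _BOUNDED_CLASSES:
        vmax = m * (1.0 - m)
        if v >= vmax:
            logger.warning("%s: infeasible beta variance %.4g clipped below %.4g",
                           spec.name, v, vmax)
            v = 0.9 * vmax
        k = m * (1.0 - m) / v - 1.0
        return ("beta", m * k, (1.0 - m) * k)
    if spec.klass in _POSITIVE_CLASSES:
        return ("gamma", m * m / v, v / m)
    sigma = np.sqrt(np.log1p(v / (m * m)))
    mu = np.log(m) - 0.5 * sigma**2
    return ("lognormal", mu, sigma)


def sample_parameter(spec: ParamSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    dist = fit_moment_distribution(spec)
    if dist[0] == "point":
        return np.full(size, dist[1])
    if dist[0] == "beta":
        return rng.beta(dist[1], dist[2], size=size)
    if dist[0] == "gamma":
        return rng.gamma(dist[1], dist[2], size=size)
    return rng.lognormal(dist[1], dist[2], size=size)


# ---------------------------------------------------------------------------
# Parameter naming and override application
# ---------------------------------------------------------------------------

_AE_KEYS = ("thrombocytopenia", "neutropenia", "anemia")


def apply_overrides(model: CEModel, overrides: Mapping[str, float]) -> CEModel:
    """Return a copy of the model with named parameters replaced.

    Recognized names: ``price_<drug>``, ``monitoring_cost``,
    ``pdl1_test_cost``, ``supportive_care_cost``,
    ``subsequent_<drug>``, ``ae_cost_<event>``, ``utility_pfs``,
    ``utility_pd``, ``prop_subsequent_<arm>``, ``prev_<stratum>``
    (prevalences renormalized to sum to 1 afterwards), and
    ``curve_<arm>_<os|pfs>_<shape|scale>``.
    """
    from dataclasses import replace as dc_replace

    m = model.copy()
    inputs = m.inputs
    for name, value in overrides.items():
        if name.startswith("price_"):
            drug = name[len("price_"):]
            if drug not in inputs.prices:
                raise KeyError(f"unknown drug in override {name!r}")
            inputs.prices[drug] = float(value)
        elif name == "monitoring_cost":
            inputs.monitoring_cost = float(value)
        elif name == "pdl1_test_cost":
            inputs.pdl1_test_cost = float(value)
        elif name == "supportive_care_cost":
            inputs.supportive_care_cost = float(value)
        elif name.startswith("subsequent_"):
            drug = name[len("subsequent_"):]
            if drug not in inputs.subsequent_cycle_costs:
                raise KeyError(f"unknown drug in override {name!r}")
            inputs.subsequent_cycle_costs[drug] = float(value)
        elif name.startswith("ae_cost_"):
            key = name[len("ae_cost_"):]
            if key not in inputs.ae_costs:
                raise KeyError(f"unknown adverse event in override {name!r}")
            inputs.ae_costs[key] = float(value)
        elif name == "utility_pfs":
            inputs.utilities["PFS"] = float(value)
        elif name == "utility_pd":
            inputs.utilities["PD"] = float(value)
        elif name.startswith("prop_subsequent_"):
            arm = name[len("prop_subsequent_"):]
            if arm not in inputs.prop_subsequent:
                raise KeyError(f"unknown arm in override {name!r}")
            inputs.prop_subsequent[arm] = float(value)
        elif name.startswith("prev_"):
            stratum = name[len("prev_"):]
            if stratum not in inputs.prevalence:
                raise KeyError(f"unknown stratum in override {name!r}")
            inputs.prevalence[stratum] = float(value)
        elif name.startswith("curve_"):
            _, arm, endpoint, par = name.split("_")
            cs = m.arm_curves[arm]
            dist = getattr(cs, endpoint)
            new = dc_replace(dist, **{par: float(value)})
            m.arm_curves[arm] = dc_replace(cs, **{endpoint: new})
        else:
            raise KeyError(f"unknown override parameter {name!r}")
    total = sum(inputs.prevalence[s] for s in STRATA)
    if abs(total - 1.0) > 1e-12 and total > 0:
        for s in STRATA:
            inputs.prevalence[s] /= total
    return m


def default_param_specs(model: CEModel, include_curves: bool = True) -> list[ParamSpec]:
    """Every tabulated cost/utility range plus proportions, prevalences
    and (optionally) survival-curve parameters at ±20%."""
    inputs = model.inputs
    specs: list[ParamSpec] = []

    def base_of(name: str) -> float:
        if name.startswith("price_"):
            return inputs.prices[name[6:]]
        if name.startswith("subsequent_"):
            return inputs.subsequent_cycle_costs[name[11:]]
        if name.startswith("ae_cost_"):
            return inputs.ae_costs[name[8:]]
        if name == "utility_pfs":
            return inputs.utilities["PFS"]
        if name == "utility_pd":
            return inputs.utilities["PD"]
        return getattr(inputs, name)

    for name, (lo, hi) in inputs.ranges.items():
        klass = "utility" if name.startswith("utility") else (
            "price" if name.startswith("price_") else "cost")
        specs.append(ParamSpec(name, base_of(name), lo, hi, klass))
    for arm, p in inputs.prop_subsequent.items():
        specs.append(ParamSpec(f"prop_subsequent_{arm}", p,
                               max(0.0, 0.8 * p), min(1.0, 1.2 * p), "proportion"))
    for stratum, w in inputs.prevalence.items():
        specs.append(ParamSpec(f"prev_{stratum}", w,
                               max(0.0, 0.8 * w), min(1.0, 1.2 * w), "proportion"))
    if include_curves:
        for arm, cs in model.arm_curves.items():
            for endpoint in ("os", "pfs"):
                dist = getattr(cs, endpoint)
                for par in ("shape", "scale"):
                    v = getattr(dist, par)
                    specs.append(ParamSpec(f"curve_{arm}_{endpoint}_{par}",
                                           v, 0.8 * v, 1.2 * v, "curve"))
    return specs


# ---------------------------------------------------------------------------
# One-way DSA
# ---------------------------------------------------------------------------

def one_way_dsa(evaluate_pair: Callable[[Mapping[str, float]], IcerOutcome],
                specs: Sequence[ParamSpec]) -> pd.DataFrame:
    """Tornado entries: the pairwise ICER at each parameter's bounds.

    ``evaluate_pair`` maps an override dict to the ICER outcome of the
    comparison of interest.  Dominance outcomes are carried as labels
    (numeric column left NaN); evaluation failures flag the entry and
    the sweep continues.  Rows are sorted by bar width descending.
    """
    rows = []
    for spec in specs:
        entry = {"parameter": spec.name, "base": spec.base,
                 "low": spec.low, "high": spec.high}
        for side, value in (("low", spec.low), ("high", spec.high)):
            try:
                out = evaluate_pair({spec.name: value})
                entry[f"icer_{side}"] = out.value if out.is_numeric else np.nan
                entry[f"label_{side}"] = out.label
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                logger.warning("DSA failed for %s=%s: %s", spec.name, value, exc)
                entry[f"icer_{side}"] = np.nan
                entry[f"label_{side}"] = f"error: {exc}"
        width = abs(entry["icer_high"] - entry["icer_low"])
        entry["width"] = width
        rows.append(entry)
    df = pd.DataFrame(rows)
    return df.sort_values("width", ascending=False, na_position="last",
                          kind="mergesort").reset_index(drop=True)


def make_pair_evaluator(model: CEModel, strategy: str, comparator: str,
                        ) -> Callable[[Mapping[str, float]], IcerOutcome]:
    """ICER of ``strategy`` vs ``comparator`` under parameter overrides."""
    by_name = {s.name: s for s in model.strategies}
    for name in (strategy, comparator):
        if name not in by_name:
            raise KeyError(f"strategy {name!r} not declared on the model")

    def evaluate(overrides: Mapping[str, float]) -> IcerOutcome:
        m = apply_overrides(model, overrides)
        return icer(m.evaluate(by_name[comparator]), m.evaluate(by_name[strategy]))

    return evaluate


# ---------------------------------------------------------------------------
# PSA and CEAC
# ---------------------------------------------------------------------------

@dataclass
class PsaResult:
    """Per-draw strategy results plus the sampled parameter values."""

    results: pd.DataFrame      # columns: draw, strategy, cost, qaly
    draws: pd.DataFrame        # one column per parameter, one row per draw
    n_failed: int
    seed: int

    def pivot(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cost = self.results.pivot(index="draw", columns="strategy", values="cost")
        qaly = self.results.pivot(index="draw", columns="strategy", values="qaly")
        return cost, qaly


def run_psa(evaluate_all: Callable[[Mapping[str, float]], Mapping[str, StrategyResult]],
            specs: Sequence[ParamSpec], n: int, seed: int) -> PsaResult:
    """Joint Monte-Carlo over all parameters, independently sampled.

    Each of the ``n`` replicates draws every parameter from its
    moment-matched distribution and re-evaluates every strategy.
    Reproducible from ``seed``; failing draws are excluded and counted.
    """
    if n < 1:
        raise ValueError("need at least one PSA draw")
    rng = np.random.default_rng(seed)
    draw_matrix = {spec.name: sample_parameter(spec, rng, n) for spec in specs}
    draws = pd.DataFrame(draw_matrix)
    rows = []
    n_failed = 0
    for i in range(n):
        overrides = {name: draws.at[i, name] for name in draws.columns}
        try:
            for name, res in evaluate_all(overrides).items():
                rows.append({"draw": i, "strategy": name,
                             "cost": res.cost, "qaly": res.qaly})
        except Exception as exc:  # noqa: BLE001 - MC loop must continue
            logger.warning("PSA draw %d failed: %s", i, exc)
            n_failed += 1
    return PsaResult(results=pd.DataFrame(rows), draws=draws,
                     n_failed=n_failed, seed=seed)


def ceac(psa: PsaResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, each strategy's probability of
    being cost-effective is the fraction of draws in which its net
    monetary benefit is maximal; exact ties share the draw equally, so
    rows sum to 1.
    """
    if psa.results.empty:
        raise ValueError("PSA produced no successful draws")
    cost, qaly = psa.pivot()
    strategies = list(cost.columns)
    c = cost.to_numpy()
    q = qaly.to_numpy()
    n_draws = c.shape[0]
    out = np.zeros((len(wtp_grid), len(strategies)))
    for i, w in enumerate(wtp_grid):
        nmb = w * q - c
        best = nmb.max(axis=1, keepdims=True)
        ties = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        out[i] = (ties / ties.sum(axis=1, keepdims=True)).sum(axis=0) / n_draws
    return pd.DataFrame(out, index=pd.Index(wtp_grid, name="wtp"), columns=strategies)
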