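"""Three-state cohort model: progression-free (PFS), progressed (PD), death.

State occupancy is derived from the overall-survival and
progression-free-survival curves in the partitioned-survival-consistent
way: ``PFS(t) = S_PFS(t)``, ``Death(t) = 1 - S_OS(t)``,
``PD(t) = S_OS(t) - S_PFS(t)`` (clamped at 0).  This is equivalent to a
time-inhomogeneous Markov chain whose per-cycle transition
probabilities are read off the two curves, and it reproduces the trial
curves by construction.

Accrual conventions: state membership is evaluated at cycle start
(TreeAge-style), no half-cycle correction by default (an optional flag
averages start/end occupancy), and discounting is applied at cycle
start with annual compounding, ``(1 + r)^(-t/12)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .survival import CYCLE_LENGTH_MONTHS, SurvivalDistribution

__all__ = ["DiscountSpec", "CohortTrace", "build_trace", "discount_factor", "accrue_outcomes"]

logger = logging.getLogger(__name__)

STATES = ("PFS", "PD", "Death")


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discount rate as a fraction per year (0.03 = 3%)."""

    annual_rate: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_rate <= 1.0:
            raise ValueError("annual discount rate must lie in [0, 1]")


def discount_factor(t_months, spec: DiscountSpec) -> np.ndarray | float:
    """Discount factor at time ``t`` (months): ``(1+rate)^(-t/12)``."""
    t = np.asarray(t_months, dtype=float)
    if np.any(t < 0):
        raise ValueError("discount time must be non-negative")
    f = (1.0 + spec.annual_rate) ** (-t / 12.0)
    return f if f.ndim else float(f)


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of the cohort.

    ``frame`` has one row per cycle with columns ``cycle``,
    ``time_months``, ``PFS``, ``PD``, ``Death``; accrual columns are
    appended by :func:`accrue_outcomes`.
    """

    frame: pd.DataFrame
    cycle_length: float
    n_clamped: int = 0

    @property
    def n_cycles(self) -> int:
        return len(self.frame)

    def occupancy(self, state: str) -> np.ndarray:
        return self.frame[state].to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def build_trace(os_dist: SurvivalDistribution, pfs_dist: SurvivalDistribution,
                horizon_years: float = 20.0,
                cycle_length: float = CYCLE_LENGTH_MONTHS) -> CohortTrace:
    """Run the cohort forward and return per-cycle state occupancy.

    Where the fitted curves cross (S_OS < S_PFS, possible with
    independently fitted extrapolations) PFS occupancy is clamped to
    S_OS and the number of clamped cycles is logged.  A warning is
    emitted if more than 0.5% of the cohort is still alive at the
    horizon, since a "lifetime" horizon should be effectively absorbing.
    """
    if horizon_years <= 0 or cycle_length <= 0:
        raise ValueError("horizon and cycle length must be positive")
    n_cycles = int(np.ceil(horizon_years * 12.0 / cycle_length))
    t = np.arange(n_cycles) * cycle_length
    s_os = np.asarray(os_dist.survival(t))
    s_pfs = np.asarray(pfs_dist.survival(t))
    n_clamped = int(np.sum(s_pfs > s_os + 1e-15))
    if n_clamped:
        logger.info("PFS curve exceeded OS curve in %d cycles; clamped", n_clamped)
    s_pfs = np.minimum(s_pfs, s_os)
    frame = pd.DataFrame({
        "cycle": np.arange(n_cycles),
        "time_months": t,
        "PFS": s_pfs,
        "PD": s_os - s_pfs,
        "Death": 1.0 - s_os,
    })
    alive_at_end = s_os[-1]
    if alive_at_end > 0.005:
        logger.warning("%.2f%% of cohort alive at horizon; consider a longer horizon",
                       100 * alive_at_end)
    return CohortTrace(frame=frame, cycle_length=cycle_length, n_clamped=n_clamped)


def accrue_outcomes(trace: CohortTrace, utilities: Mapping[str, float],
                    per_cycle_costs: Callable[[int, str], float] | Mapping[str, np.ndarray],
                    spec: DiscountSpec = DiscountSpec(),
                    half_cycle_correction: bool = False) -> tuple[float, float]:
    """Accrue discounted cost and QALYs over the trace.

    ``utilities`` maps ``PFS``/``PD`` to utility weights in [0, 1];
    death contributes nothing.  ``per_cycle_costs`` is either a
    callable ``(cycle_index, state) -> USD`` or a mapping from state to
    a per-cycle cost vector.  Returns ``(total discounted cost, total
    discounted QALY)`` and stores per-cycle accrual columns on the
    trace frame.
    """
    for st in ("PFS", "PD"):
        u = utilities[st]
        if not 0.0 <= u <= 1.0:
            raise ValueError(f"utility for {st} must lie in [0, 1], got {u}")
    n = trace.n_cycles
    t = trace.frame["time_months"].to_numpy()
    dfac = np.asarray(discount_factor(t, spec))
    dt_years = trace.cycle_length / 12.0

    cost_vectors = {}
    for st in ("PFS", "PD"):
        if callable(per_cycle_costs):
            vec = np.array([per_cycle_costs(k, st) for k in range(n)], dtype=float)
        else:
            vec = np.asarray(per_cycle_costs[st], dtype=float)
            if vec.shape != (n,):
                raise ValueError(f"cost vector for {st} must have length {n}")
        if np.any(vec < 0):
            raise ValueError("negative per-cycle costs are not allowed")
        cost_vectors[st] = vec

    occ = {st: trace.occupancy(st) for st in ("PFS", "PD")}
    if half_cycle_correction:
        for st in occ:
            o = occ[st]
            occ[st] = np.concatenate([0.5 * (o[:-1] + o[1:]), [o[-1]]])

    qaly_cycle = sum(occ[st] * utilities[st] for st in ("PFS", "PD")) * dt_years
    cost_cycle = sum(occ[st] * cost_vectors[st] for st in ("PFS", "PD"))

    trace.frame["cost"] = cost_cycle
    trace.frame["qaly"] = qaly_cycle
    trace.frame["disc_cost"] = cost_cycle * dfac
    trace.frame["disc_qaly"] = qaly_cycle * dfac
    return float(np.sum(cost_cycle * dfac)), float(np.sum(qaly_cycle * dfac))
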