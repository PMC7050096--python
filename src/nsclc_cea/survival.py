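"""Parametric survival distributions for state-transition modelling.

Two families are supported, both in the accelerated-failure-time
shape/scale parameterization with time measured in months:

* Weibull:       ``S(t) = exp(-(t/scale)^shape)``
* log-logistic:  ``S(t) = 1 / (1 + (t/scale)^shape)``

The parameterization is stated explicitly because health-economic
models are routinely broken by silently mismatched conventions (e.g.
rate vs scale, log-scale intercepts).  ``scale`` is in months and for
the log-logistic equals the median survival time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "CYCLE_LENGTH_MONTHS",
    "SurvivalDistribution",
    "goodness_of_fit_r2",
]

#: One model cycle is 3 weeks.  Months are defined via the mean Gregorian
#: month of 30.4375 days, so a cycle is 21 / 30.4375 ≈ 0.6899 months.
CYCLE_LENGTH_MONTHS: float = 21.0 / 30.4375

Family = Literal["weibull", "loglogistic"]
_FAMILIES = ("weibull", "loglogistic")


@dataclass(frozen=True)
class SurvivalDistribution:
    """A Weibull or log-logistic survival distribution.

    Parameters
    ----------
    family
        ``"weibull"`` or ``"loglogistic"``.
    shape
        Dimensionless shape parameter, > 0.  Shape 1 gives the
        exponential (Weibull) or a log-logistic with monotone
        decreasing hazard.
    scale
        Scale parameter in months, > 0.
    """

    family: Family
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError(f"shape must be a positive finite real, got {self.shape}")
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError(f"scale must be a positive finite real, got {self.scale}")

    # -- core quantities -------------------------------------------------

    def survival(self, t):
        """Survival probability S(t) at time ``t`` (months).

        Accepts scalars or arrays; negative times raise.
        """
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("survival time must be non-negative")
        z = (t_arr / self.scale) ** self.shape
        if self.family == "weibull":
            s = np.exp(-z)
        else:
            s = 1.0 / (1.0 + z)
        return s if s.ndim else float(s)

    def quantile(self, u):
        """Time t with S(t) = u, for u in (0, 1]."""
        u_arr = np.asarray(u, dtype=float)
        if np.any((u_arr <= 0) | (u_arr > 1)):
            raise ValueError("survival quantile requires u in (0, 1]")
        if self.family == "weibull":
            t = self.scale * (-np.log(u_arr)) ** (1.0 / self.shape)
        else:
            t = self.scale * (1.0 / u_arr - 1.0) ** (1.0 / self.shape)
        return t if t.ndim else float(t)

    def median(self) -> float:
        """Median survival time in months (S(median) = 0.5)."""
        if self.family == "weibull":
            return self.scale * np.log(2.0) ** (1.0 / self.shape)
        return self.scale

    def per_cycle_transition(self, cycle_index: int, cycle_length: float = CYCLE_LENGTH_MONTHS) -> float:
        """Conditional probability of the event during one model cycle.

        ``p_k = 1 - S((k+1)Δ) / S(kΔ)`` for cycle ``k`` — the
        time-varying transition probability of a Markov cohort model
        whose event-free curve is this distribution.  In the far tail
        where S(t) underflows to 0 the cohort is absorbed (p = 1).
        """
        if cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if cycle_index < 0:
            raise ValueError("cycle_index must be >= 0")
        t = cycle_index * cycle_length
        s_now = self.survival(t)
        if s_now <= 0.0:
            return 1.0
        p = 1.0 - self.survival(t + cycle_length) / s_now
        return float(min(max(p, 0.0), 1.0))

    # -- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {"family": self.family, "shape": float(self.shape), "scale": float(self.scale)}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalDistribution":
        return cls(family=d["family"], shape=float(d["shape"]), scale=float(d["scale"]))


def goodness_of_fit_r2(predicted: Iterable[float], observed: Iterable[float]) -> float:
    """Coefficient of determination of predicted vs observed survival.

    ``r² = 1 - SS_res / SS_tot`` with the total sum of squares taken
    about the mean of the observed values.  Used to validate parametric
    fits against digitized trial curves.  If the observed series has
    zero variance the statistic is degenerate: returns 1.0 when the
    prediction is exact and ``-inf`` otherwise rather than dividing by
    zero.
    """
    pred = np.asarray(list(predicted), dtype=float)
    obs = np.asarray(list(observed), dtype=float)
    if pred.shape != obs.shape or obs.size == 0:
        raise ValueError("predicted and observed must be equal-length, non-empty")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else float("-inf")
    return 1.0 - ss_res / ss_tot
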