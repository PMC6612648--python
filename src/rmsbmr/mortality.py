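"""Logistic mortality model driven by the metabolic decline F(T).

The annual death probability of men past 80 is modelled as a logistic
function of the renormalized msBMR:

    P(T) = exp(G(T)) / (1 + exp(G(T))),   G(T) = C * (F(T_c) - F(T)),

where T_c is the age at which the modelled mortality rate reaches 0.5 and C
a dimensionless slope.  Because F declines exponentially, P behaves like a
Gompertz hazard at younger ages and saturates in centenarians.  The observed
mortality plateau is represented by freezing F at its value at the plateau
age (default 108), which makes P constant (= 0.678 under the US parameters)
for all later ages — interpreted as the lowest msBMR compatible with life.

Survival curves are built as yearly products S(T+1) = S(T) * (1 - P(T))
anchored at S(anchor) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .metabolic import DEFAULT_DECAY_LAW, DecayLaw, universal_decline

#: Fitted (C, T_c) per national dataset.
US_PARAMS = (1.55, 101.0)
ITALY_PARAMS = (1.4, 101.0)
JAPAN_PARAMS = (1.5, 102.0)

#: Age from which the mortality rate is held constant (the observed
#: centenarian plateau).
DEFAULT_PLATEAU_AGE = 108.0


@dataclass(frozen=True)
class MortalityModel:
    """Logistic mortality model P(T) on top of a :class:`DecayLaw`.

    ``plateau_age=None`` disables the centenarian plateau.
    """

    c: float = US_PARAMS[0]
    t_c: float = US_PARAMS[1]
    law: DecayLaw = field(default_factory=DecayLaw)
    plateau_age: float | None = DEFAULT_PLATEAU_AGE

    def __post_init__(self) -> None:
        if not self.c >= 0:
            raise ValueError("C must be non-negative")
        if not self.t_c > 0:
            raise ValueError("T_c must be positive")


def mortality_rate(age, model: MortalityModel):
    """Annual death probability P(T); array-aware, ages >= 16.

    For ages at or past the plateau, F is clamped at F(plateau_age) so the
    rate is constant there.
    """
    age = np.asarray(age, dtype=float)
    if np.any(age < 16):
        raise ValueError("model defined for ages >= 16")
    t_eff = age if model.plateau_age is None else np.minimum(
        age, model.plateau_age)
    g = model.c * (universal_decline(model.t_c, model.law)
                   - np.asarray(universal_decline(t_eff, model.law)))
    p = expit(g)
    return p if p.ndim else float(p)


def survival_curve(model: MortalityModel, anchor_age: int = 80,
                   end_age: int = 120) -> pd.DataFrame:
    """Survival S(T) on integer ages with S(anchor_age) = 1.

    S(T+1) = S(T) * (1 - P(T)); returns DataFrame ``age, survival``.
    """
    if not anchor_age < end_age:
        raise ValueError("anchor_age must be < end_age")
    ages = np.arange(anchor_age, end_age + 1)
    p = np.atleast_1d(mortality_rate(ages[:-1], model))
    s = np.concatenate([[1.0], np.cumprod(1.0 - p)])
    return pd.DataFrame({"age": ages, "survival": s})


class DegenerateSeriesError(ValueError):
    """Mortality series carries no usable information for the fit."""


def fit_mortality(series: pd.DataFrame, law: DecayLaw = DEFAULT_DECAY_LAW,
                  age_range: tuple[float, float] = (80, 104),
                  fixed_t_c: float | None = None) -> tuple[float, float]:
    """Fit (C, T_c) of the logistic model to an observed rate series.

    Least squares on the logit scale.  Since
    ``logit(P(T)) = C*F(T_c) - C*F(T)`` is affine in F(T), the joint
    optimum over (C, T_c) is an ordinary regression of logit(rate) on F(T):
    the slope gives -C and the intercept gives C*F(T_c), from which T_c
    follows by inverting F.  With ``fixed_t_c`` given, only C is estimated
    (regression through the origin on F(T_c) - F(T)).

    ``series`` needs columns ``age, rate``; rates must lie strictly inside
    (0, 1) and at least 4 ages must fall in ``age_range`` (the pre-plateau
    window by default).
    """
    sub = series[(series["age"] >= age_range[0])
                 & (series["age"] <= age_range[1])]
    rate = sub["rate"].to_numpy(dtype=float)
    ok = (rate > 0) & (rate < 1)
    rate, ages = rate[ok], sub["age"].to_numpy(dtype=float)[ok]
    if ages.size < 4:
        raise DegenerateSeriesError(
            "need >=4 ages with rates strictly inside (0,1) in the fit window")
    y = logit(rate)
    f = np.asarray(universal_decline(ages, law))

    if fixed_t_c is not None:
        x = universal_decline(fixed_t_c, law) - f
        denom = float(x @ x)
        if denom == 0:
            raise DegenerateSeriesError("F(T) constant over the fit window")
        return float((x @ y) / denom), float(fixed_t_c)

    if np.ptp(f) == 0 or np.ptp(y) == 0:
        raise DegenerateSeriesError("constant rates or ages: fit undetermined")
    slope, intercept = np.polyfit(f, y, 1)
    c = -float(slope)
    if c <= 0:
        raise DegenerateSeriesError(
            "fitted slope implies non-increasing mortality with age")
    f_tc = float(intercept) / c
    if not 0 < f_tc < law.f0:
        raise DegenerateSeriesError(
            f"implied F(T_c)={f_tc:.3f} outside (0, F0); cannot invert F")
    if law.u == 0:
        raise DegenerateSeriesError("decay law with u=0: T_c unidentifiable")
    t_c = -np.log(f_tc / law.f0) / law.u
    return c, float(t_c)
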