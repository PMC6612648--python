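"""Harris-Benedict mass-specific BMR and the universal metabolic decline F(T).

The mass-specific basal metabolic rate (msBMR, kcal day^-1 kg^-1) of an adult
man is computed from the Harris-Benedict equation (HBE)

    msBMR = (88.362 + 13.397*W + 4.799*H - 5.677*T) / W

with weight W (kg), height H (cm) and age T (years).  After renormalization
(see :mod:`rmsbmr.renormalize`) the msBMR of every subject collapses onto a
single exponential decline

    F(T) = F0 * exp(-u * T)

with F0 = 27.63 kcal day^-1 kg^-1 and decay constant u = 0.00364 / year.
This module also provides the age-binned cohort statistics and the
SD-convergence extrapolation used to locate the age at which inter-individual
variation of msBMR and BMI vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# Harris-Benedict coefficients (male form): BMR = a + b*W + c*H - d*T
HBE_INTERCEPT = 88.362
HBE_WEIGHT = 13.397
HBE_HEIGHT = 4.799
HBE_AGE = 5.677

#: Large-weight asymptote of the mass-specific HBE.
HBE_ASYMPTOTE = HBE_WEIGHT


class MetabolicDomainError(ValueError):
    """Raised for physically impossible anthropometric inputs."""


@dataclass(frozen=True)
class DecayLaw:
    """The universal decline F(T) = f0 * exp(-u*T) of the renormalized msBMR.

    Parameters
    ----------
    f0 : float
        msBMR extrapolated to age 0, kcal day^-1 kg^-1.  Default 27.63.
    u : float
        Decay constant, year^-1.  Default 0.00364 (a 0.36 % loss per year).
    """

    f0: float = 27.63
    u: float = 0.00364

    def __post_init__(self) -> None:
        if not self.f0 > 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if self.u < 0:
            raise ValueError(f"u must be non-negative, got {self.u}")

    def __call__(self, age):
        return universal_decline(age, self)


#: The decay law fitted on the renormalized American male cohort.
DEFAULT_DECAY_LAW = DecayLaw()


def hbe_msbmr(weight, height, age):
    """Mass-specific BMR from the Harris-Benedict equation (male form).

    Parameters are weight (kg), height (cm) and age (years); scalars or
    arrays.  Returns kcal day^-1 kg^-1.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(weight <= 0):
        raise MetabolicDomainError("weight must be positive")
    if np.any(height <= 0):
        raise MetabolicDomainError("height must be positive")
    out = (HBE_INTERCEPT + HBE_WEIGHT * weight + HBE_HEIGHT * height
           - HBE_AGE * age) / weight
    return out if out.ndim else float(out)


def universal_decline(age, law: DecayLaw = DEFAULT_DECAY_LAW):
    """Evaluate F(T) = f0*exp(-u*T) at age T (years)."""
    age = np.asarray(age, dtype=float)
    out = law.f0 * np.exp(-law.u * age)
    return out if out.ndim else float(out)


def bin_stats(cohort: pd.DataFrame, min_bin: int = 10) -> pd.DataFrame:
    """Age-binned mean/SD of msBMR and BMI for an anthropometric cohort.

    Parameters
    ----------
    cohort : DataFrame
        Columns ``age`` (integer years), ``height_cm``, ``weight_kg``.
        A ``bmi`` column is used if present, else computed.
    min_bin : int
        Sample SDs are reported only for bins with at least this many
        subjects (sample SD, n-1 denominator); smaller bins get NaN.

    Returns
    -------
    DataFrame with columns ``age, n, msbmr_mean, msbmr_sd, bmi_mean, bmi_sd``,
    one row per observed integer age, ascending.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    df = cohort.copy()
    df["_msbmr"] = hbe_msbmr(df["weight_kg"], df["height_cm"], df["age"])
    if "bmi" not in df.columns:
        df["bmi"] = df["weight_kg"] / (df["height_cm"] / 100.0) ** 2
    g = df.groupby("age")
    out = pd.DataFrame({
        "age": np.asarray(sorted(g.groups)),
        "n": g.size().sort_index().to_numpy(),
        "msbmr_mean": g["_msbmr"].mean().sort_index().to_numpy(),
        "msbmr_sd": g["_msbmr"].std(ddof=1).sort_index().to_numpy(),
        "bmi_mean": g["bmi"].mean().sort_index().to_numpy(),
        "bmi_sd": g["bmi"].std(ddof=1).sort_index().to_numpy(),
    })
    small = out["n"] < min_bin
    out.loc[small, ["msbmr_sd", "bmi_sd"]] = np.nan
    return out.reset_index(drop=True)


_SERIES = {
    "msbmr_mean": ("msbmr_mean", 0),
    "msbmr_sd": ("msbmr_sd", 0),
    "bmi_mean": ("bmi_mean", 0),
    "bmi_sd": ("bmi_sd", 0),
    "msbmr_upper": ("msbmr_mean", +1),   # mean + SD
    "msbmr_lower": ("msbmr_mean", -1),   # mean - SD
    "bmi_upper": ("bmi_mean", +1),
    "bmi_lower": ("bmi_mean", -1),
}


def quadratic_summary(stats: pd.DataFrame, series: str,
                      age_range: tuple[float, float] = (45, 80)):
    """Least-squares quadratic a*T**2 + b*T + c through one binned statistic.

    ``series`` is one of ``msbmr_mean``, ``msbmr_sd``, ``bmi_mean``,
    ``bmi_sd`` or the composite bands ``msbmr_upper``/``msbmr_lower``
    (mean +/- SD) and ``bmi_upper``/``bmi_lower``.  Returns (a, b, c).
    """
    if series not in _SERIES:
        raise ValueError(f"unknown series {series!r}; one of {sorted(_SERIES)}")
    col, sd_sign = _SERIES[series]
    lo, hi = age_range
    sub = stats[(stats["age"] >= lo) & (stats["age"] <= hi)]
    y = sub[col].to_numpy(dtype=float)
    if sd_sign:
        y = y + sd_sign * sub[col.split("_")[0] + "_sd"].to_numpy(dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError(
            f"need >=3 populated bins in {age_range} to fit a quadratic, "
            f"got {int(ok.sum())}")
    a, b, c = np.polyfit(sub["age"].to_numpy(dtype=float)[ok], y[ok], 2)
    return float(a), float(b), float(c)


class NonConvergentError(RuntimeError):
    """The extrapolated mean+SD and mean-SD curves do not intersect."""


def convergence_age(upper_fit, lower_fit, age_max: float = 80.0,
                    horizon: float = 200.0) -> tuple[float, float]:
    """Extrapolated age at which the mean+SD and mean-SD quadratics meet.

    Solves upper(T) = lower(T) analytically from the quadratic difference and
    returns the smallest intersection age in (age_max, horizon] together with
    the common value there.  If the two fits are identical the SD is already
    zero and (age_max, value) is returned.  Raises
    :class:`NonConvergentError` when no real intersection exists in range.
    """
    du = np.asarray(upper_fit, dtype=float) - np.asarray(lower_fit, dtype=float)
    if np.allclose(du, 0.0, atol=1e-12):
        val = float(np.polyval(upper_fit, age_max))
        return float(age_max), val
    roots = np.roots(du)
    real = roots[np.abs(roots.imag) < 1e-9].real
    in_range = np.sort(real[(real > age_max) & (real <= horizon)])
    if in_range.size == 0:
        raise NonConvergentError(
            f"extrapolated bands do not intersect in ({age_max}, {horizon}]")
    t = float(in_range[0])
    value = 0.5 * (np.polyval(upper_fit, t) + np.polyval(lower_fit, t))
    return t, float(value)
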