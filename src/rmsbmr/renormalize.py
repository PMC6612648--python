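"""Two-step renormalization of the msBMR onto the universal decline F(T).

Step 1 (*first renormalization*) replaces each subject's recorded weight by
the weight a BMI of 21.5 kg/m^2 would give at his height,
``W1 = (H/100)^2 * 21.5``, and evaluates the Harris-Benedict msBMR there.
This removes most of the weight-driven dispersion but leaves a height trend:
tall men fall below, short men above, the common curve.

Step 2 (*second renormalization*) readjusts the weight so the msBMR equals
the universal decline F(T) exactly.  Because the HBE is linear in weight the
readjusted weight has the closed form

    W2 = (88.362 + 4.799*H - 5.677*T) / (F(T) - 13.397),

the unique positive solution of msBMR(W, H, T) = F(T), defined whenever
F(T) exceeds the large-weight asymptote 13.397 of the mass-specific HBE.

``fit_decay_law`` estimates (F0, u) by ordinary least squares of
log(msBMR) on age, which on first-renormalized per-age means recovers
u = 0.00364 / year.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metabolic import (DEFAULT_DECAY_LAW, HBE_AGE, HBE_ASYMPTOTE,
                        HBE_HEIGHT, HBE_INTERCEPT, DecayLaw, hbe_msbmr,
                        universal_decline)

#: Reference BMI used by the first renormalization (kg/m^2); the convergence
#: value of the cohort BMI at age 105 and the middle of the healthy range.
DEFAULT_BMI_REF = 21.5


class InfeasibleRenormalizationError(ValueError):
    """F(T) at or below the HBE large-weight asymptote (13.397): no
    positive weight can bring the msBMR down to the target."""


def first_renorm(height_cm, age, bmi_ref: float = DEFAULT_BMI_REF):
    """First renormalization: weight implied by a reference BMI.

    Returns ``(weight, msbmr)`` with weight = (H/100)^2 * bmi_ref and the
    HBE msBMR evaluated at that weight.  The subject's recorded weight plays
    no role.  Array-aware.
    """
    if not bmi_ref > 0:
        raise ValueError("bmi_ref must be positive")
    height_cm = np.asarray(height_cm, dtype=float)
    weight = (height_cm / 100.0) ** 2 * bmi_ref
    msbmr = hbe_msbmr(weight, height_cm, age)
    return (weight if weight.ndim else float(weight), msbmr)


def second_renorm(height_cm, age, law: DecayLaw = DEFAULT_DECAY_LAW):
    """Second renormalization: weight solving msBMR(W, H, T) = F(T).

    Returns ``(weight, bmi)`` at full precision; see
    :func:`printed_second_renorm` for the tabulated convention.  Raises
    :class:`InfeasibleRenormalizationError` where F(T) <= 13.397.
    """
    height_cm = np.asarray(height_cm, dtype=float)
    age = np.asarray(age, dtype=float)
    f = np.asarray(universal_decline(age, law))
    if np.any(f <= HBE_ASYMPTOTE):
        raise InfeasibleRenormalizationError(
            f"F(T) <= {HBE_ASYMPTOTE} (the HBE large-weight asymptote); "
            "no positive weight attains the target msBMR")
    weight = (HBE_INTERCEPT + HBE_HEIGHT * height_cm - HBE_AGE * age) \
        / (f - HBE_ASYMPTOTE)
    bmi = weight / (height_cm / 100.0) ** 2
    if weight.ndim:
        return weight, bmi
    return float(weight), float(bmi)


def printed_second_renorm(height_cm: float, age: float,
                          law: DecayLaw = DEFAULT_DECAY_LAW):
    """Second renormalization with the tabulation convention: the weight is
    rounded to 0.1 kg and the BMI (2 d.p.) is computed from that rounded
    weight, matching how the worked samples are printed."""
    weight, _ = second_renorm(height_cm, age, law)
    w = round(float(weight), 1)
    return w, round(w / (height_cm / 100.0) ** 2, 2)


def fit_decay_law(ages, msbmr_means, age_range=None) -> DecayLaw:
    """Fit F(T) = F0*exp(-u*T) by OLS of log(msBMR) on age.

    ``ages`` and ``msbmr_means`` are parallel arrays (typically per-age means
    of the first-renormalized msBMR).  ``age_range=(lo, hi)`` optionally
    restricts the fit window.  Values must be positive.
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(msbmr_means, dtype=float)
    if age_range is not None:
        keep = (ages >= age_range[0]) & (ages <= age_range[1])
        ages, y = ages[keep], y[keep]
    ok = np.isfinite(y) & np.isfinite(ages)
    ages, y = ages[ok], y[ok]
    if ages.size < 3:
        raise ValueError("need at least 3 ages to fit the decay law")
    if np.any(y <= 0):
        raise ValueError("msBMR values must be positive for the log fit")
    slope, intercept = np.polyfit(ages, np.log(y), 1)
    u = float(-slope)
    if -1e-12 < u < 0:   # constant data: clamp floating noise
        u = 0.0
    if u < 0:
        raise ValueError(
            f"fitted decay constant is negative ({u:.3g}): the series grows "
            "with age and is not described by an exponential decline")
    return DecayLaw(f0=float(np.exp(intercept)), u=u)


def renormalize_cohort(cohort: pd.DataFrame,
                       law: DecayLaw = DEFAULT_DECAY_LAW,
                       bmi_ref: float = DEFAULT_BMI_REF) -> pd.DataFrame:
    """Apply both renormalization steps to every subject of a cohort table.

    Input columns: ``id, age, height_cm`` (``weight_kg`` is ignored by
    construction).  Output columns: ``id, age, height_cm, first_weight,
    first_msbmr, second_weight, second_bmi, target_msbmr``.  Subjects whose
    age is infeasible under ``law`` get NaN in the second-step columns.
    """
    if len(cohort) == 0:
        return pd.DataFrame(columns=[
            "id", "age", "height_cm", "first_weight", "first_msbmr",
            "second_weight", "second_bmi", "target_msbmr"])
    h = cohort["height_cm"].to_numpy(dtype=float)
    t = cohort["age"].to_numpy(dtype=float)
    w1, m1 = first_renorm(h, t, bmi_ref)
    f = np.asarray(universal_decline(t, law))
    feasible = f > HBE_ASYMPTOTE
    w2 = np.full_like(h, np.nan)
    bmi2 = np.full_like(h, np.nan)
    if feasible.any():
        w2[feasible], bmi2[feasible] = second_renorm(
            h[feasible], t[feasible], law)
    return pd.DataFrame({
        "id": cohort["id"].to_numpy(),
        "age": cohort["age"].to_numpy(),
        "height_cm": h,
        "first_weight": w1,
        "first_msbmr": m1,
        "second_weight": w2,
        "second_bmi": bmi2,
        "target_msbmr": f,
    })
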