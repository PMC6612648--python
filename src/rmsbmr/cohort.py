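"""Seeded synthetic anthropometric cohorts and mortality-rate series.

The study inputs were a national anthropometric survey of adult men and
national age-indexed mortality rates.  Neither is redistributable here, so
this module generates synthetic stand-ins with the statistical structure the
analysis assumes:

* a male cohort aged 16-80 drawn from five population groups with different
  height distributions, whose BMI dispersion shrinks linearly with age so
  that the extrapolated BMI SD reaches 0 at age 105 with mean BMI 21.5 —
  the convergence point the renormalization is anchored to;
* mortality-rate series drawn from a :class:`~rmsbmr.mortality.MortalityModel`
  with optional binomial sampling noise, for parameter-recovery tests.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd


class CohortConfigError(ValueError):
    """Invalid cohort specification (proportions, dispersions, age range)."""


#: Convergence endpoints of the default BMI curves.
BMI_CONVERGENCE_AGE = 105.0
BMI_CONVERGENCE_VALUE = 21.5
_BMI_MEAN_16 = 26.1
_BMI_SD_16 = 5.0


def default_bmi_mean(age):
    """Linear mean-BMI curve: 26.1 at age 16 down to 21.5 at age 105."""
    age = np.asarray(age, dtype=float)
    slope = (BMI_CONVERGENCE_VALUE - _BMI_MEAN_16) / (BMI_CONVERGENCE_AGE - 16.0)
    out = _BMI_MEAN_16 + slope * (age - 16.0)
    return out if out.ndim else float(out)


def default_bmi_sd(age):
    """Linear BMI-SD curve: 5.0 at age 16, reaching 0 at age 105."""
    age = np.asarray(age, dtype=float)
    out = _BMI_SD_16 * np.clip((BMI_CONVERGENCE_AGE - age)
                               / (BMI_CONVERGENCE_AGE - 16.0), 0.0, None)
    return out if out.ndim else float(out)


# Group labels follow the five self-reported origin categories of US health
# surveys; the height means are placeholders — only their ordering matters
# for demonstrating the height effect removed by the second renormalization.
DEFAULT_GROUPS: dict[str, float] = {
    "white": 0.35, "black": 0.25, "mexican_american": 0.18,
    "other_hispanic": 0.12, "asian": 0.10,
}
DEFAULT_HEIGHTS: dict[str, tuple[float, float]] = {
    "white": (178.0, 7.0), "black": (177.0, 7.0),
    "mexican_american": (170.0, 7.0), "other_hispanic": (168.0, 7.0),
    "asian": (165.0, 7.0),
}


@dataclass
class CohortSpec:
    """Configuration of a synthetic male cohort.

    ``group_mix`` maps group label -> proportion (must sum to 1);
    ``height_params`` maps group label -> (mean cm, SD cm);
    ``bmi_mean_curve``/``bmi_sd_curve`` map age -> BMI mean/SD.
    """

    n_subjects: int = 25_425
    age_min: int = 16
    age_max: int = 80
    group_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUPS))
    height_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_HEIGHTS))
    bmi_mean_curve: Callable = default_bmi_mean
    bmi_sd_curve: Callable = default_bmi_sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be >= 1")
        if not self.age_min < self.age_max:
            raise CohortConfigError("age_min must be < age_max")
        total = float(sum(self.group_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise CohortConfigError(
                f"group proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.group_mix.values()):
            raise CohortConfigError("group proportions must be >= 0")
        for label in self.group_mix:
            if label not in self.height_params:
                raise CohortConfigError(f"no height_params for group {label!r}")
            if self.height_params[label][1] < 0:
                raise CohortConfigError(f"negative height SD for {label!r}")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort table from ``spec``.

    Ages are integers uniform on [age_min, age_max].  Heights are normal per
    group; BMI is normal with the age-dependent mean/SD curves, truncated
    below at physiological floors (height 130 cm, BMI 12) so weights stay
    positive.  Weight is derived as (H/100)^2 * BMI exactly.

    Returns a DataFrame with columns ``id, age, height_cm, weight_kg, bmi,
    group``, byte-identical across runs with the same spec.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_subjects
    labels = list(spec.group_mix)
    props = np.array([spec.group_mix[g] for g in labels], dtype=float)
    props = props / props.sum()

    age = rng.integers(spec.age_min, spec.age_max + 1, size=n)
    group_idx = rng.choice(len(labels), size=n, p=props)
    means = np.array([spec.height_params[g][0] for g in labels])
    sds = np.array([spec.height_params[g][1] for g in labels])
    height = rng.normal(means[group_idx], sds[group_idx])
    height = np.maximum(height, 130.0)

    bmi_mu = np.asarray(spec.bmi_mean_curve(age), dtype=float)
    bmi_sd = np.asarray(spec.bmi_sd_curve(age), dtype=float)
    if np.any(bmi_sd < 0):
        raise CohortConfigError("bmi_sd_curve produced a negative SD")
    bmi = rng.normal(bmi_mu, bmi_sd)
    bmi = np.maximum(bmi, 12.0)
    weight = (height / 100.0) ** 2 * bmi

    return pd.DataFrame({
        "id": [f"S{i:06d}" for i in range(n)],
        "age": age.astype(int),
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "group": [labels[i] for i in group_idx],
    })


def generate_mortality_series(model, ages, n_at_risk: int | None = None,
                              seed: int | None = None) -> pd.DataFrame:
    """Synthetic age-indexed mortality rates from a mortality model.

    With ``n_at_risk`` given, the rate at each age is drawn as
    Binomial(n_at_risk, P(T)) / n_at_risk; with ``n_at_risk=None`` the exact
    model rate P(T) is returned (noise off).

    Returns a DataFrame ``age, rate`` (plus ``n_at_risk`` when noisy).
    """
    from .mortality import mortality_rate  # local import to avoid a cycle

    ages = np.asarray(ages)
    if np.any(ages < 16):
        raise ValueError("mortality model is defined for ages >= 16")
    p = np.atleast_1d(mortality_rate(ages, model))
    if n_at_risk is None:
        return pd.DataFrame({"age": ages, "rate": p})
    if n_at_risk < 1:
        raise ValueError("n_at_risk must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    deaths = rng.binomial(n_at_risk, p)
    return pd.DataFrame({
        "age": ages,
        "rate": deaths / float(n_at_risk),
        "n_at_risk": np.full(ages.shape, n_at_risk, dtype=int),
    })
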