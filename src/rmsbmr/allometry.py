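"""Allometric scaling of BMR from organ-weight redistribution.

Starting from the renormalized organ weights of the reference male, the
body mass is swept from 1 to 800 kg in small steps.  Each +/-0.5 kg change
is split across organs proportionally to msBMR_k^-q with q = 1.05 (q = 1.4
for the brain, whose starting weight is also reduced to 1/8 of the human
value: the human brain is an outlier among mammals).  Low-metabolic-rate
tissues (adipose, residual) therefore absorb most of the mass growth, which
dilutes the whole-body metabolic rate as mass increases, and on the way down
they are depleted first (organ masses are floored at zero and the shortfall
redistributed), which enriches the small bodies in high-rate organs.  The
resulting BMR(M) = sum_k W_k * msBMR_k reproduces the empirical 3/4-power
scaling law over 1-800 kg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .organs import ReferenceMale

_COLUMNS = ("mass_kg", "muscle", "liver", "brain", "heart", "kidneys",
            "adipose", "residual", "bmr_kcal_day")


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of the body-mass sweep."""

    step: float = 0.5                 # kg per iteration
    mass_min: float = 1.0             # kg
    mass_max: float = 800.0           # kg
    q_general: float = 1.05           # redistribution exponent
    q_brain: float = 1.4              # brain-specific exponent
    brain_start_fraction: float = 1.0 / 8.0
    start_mass: float = 67.0          # reference body mass seeding the sweep

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ValueError("step must be positive")
        if not 0 < self.mass_min < self.mass_max:
            raise ValueError("need 0 < mass_min < mass_max")
        if not self.mass_min <= self.start_mass <= self.mass_max:
            raise ValueError("start_mass must lie inside the mass range")


def _shares(msbmr_k: np.ndarray, q_k: np.ndarray,
            active: np.ndarray) -> np.ndarray:
    s = np.where(active, msbmr_k ** (-q_k), 0.0)
    return s / s.sum()


def _remove(w: np.ndarray, amount: float, msbmr_k: np.ndarray,
            q_k: np.ndarray) -> np.ndarray:
    """Remove ``amount`` kg with msBMR^-q shares, flooring organs at zero
    and redistributing any shortfall among the organs still populated."""
    w = w.copy()
    remaining = amount
    active = w > 0
    while remaining > 1e-15 and active.any():
        take = remaining * _shares(msbmr_k, q_k, active)
        over = take >= w
        if not (over & active).any():
            w -= take
            break
        freed = w[over & active].sum()
        w[over & active] = 0.0
        remaining -= freed
        active = w > 0
    return w


def sweep_body_mass(reference: ReferenceMale,
                    config: SweepConfig = SweepConfig()) -> pd.DataFrame:
    """Sweep body mass across ``config``'s range from the reference male.

    The initial organ vector is the reference's renormalized organ weights
    with the brain scaled by ``brain_start_fraction`` (the freed mass is not
    reassigned, so the sweep starts slightly below ``start_mass``).  Mass is
    added up to ``mass_max`` and removed down to ``mass_min`` in steps of
    ``config.step`` (final partial steps land exactly on the bounds), with
    per-step shares ~ msBMR_k(r)^-q_k under one joint normalization.

    Returns a DataFrame with columns ``mass_kg, muscle, liver, brain, heart,
    kidneys, adipose, residual, bmr_kcal_day``, ascending in mass.
    BMR per row = sum_k W_k * msBMR_k(r).
    """
    if np.any(reference.w_k_r <= 0):
        raise ValueError("reference organ masses must be positive")
    msbmr_k = reference.msbmr_k.astype(float)
    q_k = np.full(msbmr_k.shape, config.q_general)
    brain_idx = reference.labels.index("brain")
    q_k[brain_idx] = config.q_brain

    w0 = reference.w_k_r.astype(float).copy()
    w0[brain_idx] *= config.brain_start_fraction
    start = w0.sum()

    def row(w: np.ndarray) -> list[float]:
        return [w.sum(), *w, float((w * msbmr_k).sum())]

    up: list[list[float]] = [row(w0)]
    w, m = w0.copy(), start
    while m < config.mass_max - 1e-12:
        step = min(config.step, config.mass_max - m)
        w = w + step * _shares(msbmr_k, q_k, np.ones_like(w, dtype=bool))
        m += step
        up.append(row(w))

    down: list[list[float]] = []
    w, m = w0.copy(), start
    while m > config.mass_min + 1e-12:
        step = min(config.step, m - config.mass_min)
        w = _remove(w, step, msbmr_k, q_k)
        m -= step
        down.append(row(w))

    data = down[::-1] + up
    return pd.DataFrame(data, columns=list(_COLUMNS))


def loglog_slope(table: pd.DataFrame,
                 mass_range: tuple[float, float] | None = None) -> float:
    """Least-squares slope of log BMR against log body mass.

    ``mass_range=(lo, hi)`` restricts the fit; the scaling exponent of an
    exact power law BMR = a*M^b is recovered as b.
    """
    mass = table["mass_kg"].to_numpy(dtype=float)
    bmr = table["bmr_kcal_day"].to_numpy(dtype=float)
    if mass_range is not None:
        keep = (mass >= mass_range[0]) & (mass <= mass_range[1])
        mass, bmr = mass[keep], bmr[keep]
    if mass.size < 3 or np.ptp(np.log(mass)) == 0:
        raise ValueError("need >=3 rows spanning a non-degenerate mass range")
    slope, _ = np.polyfit(np.log(mass), np.log(bmr), 1)
    return float(slope)
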