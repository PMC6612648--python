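"""Mitochondrial fusion/fission transport dynamics.

Within a standard cell, mitochondria cycle between a fission state (count
N1) and a fusion state (count N2) while biogenesis adds and mitophagy
removes organelles from the fission pool:

    N2' = -P21*N2 + P12*N1
    N1' = -(P12 + P13 - P11)*N1 + P21*N2

with per-year transition rates P12 (fission->fusion), P21 (fusion->fission),
biogenesis P11 and mitophagy P13.  Eliminating N1 gives
N2'' + B*N2' + C*N2 = 0 with B = P12 + P21 + P13 - P11 and
C = P21*(P13 - P11); the slow characteristic root

    u = (B - sqrt(B^2 - 4C)) / 2

governs the long-time behaviour: the total N1 + N2 decays as a single
exponential exp(-u*T), and for fast exchange (P12 + P21 >> |P13 - P11|) u
reduces to P21*(P13 - P11)/(P12 + P21).  With the turnover-time identity
N1*P11*TOT = N1 + N2 this becomes u = (P13 - P11)/(P11*TOT): a decades-long
metabolic decline emerges from a per-mill imbalance between mitophagy and
biogenesis.  Time is measured in years throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

#: Mouse-liver adult decline parameters (density units of the measurements).
MOUSE_F0 = 58.0
MOUSE_T_OFFSET = 0.5          # years; end of development
MOUSE_LIFESPAN_RATIO = 30.0   # 120-year human span : 4-year mouse span
MOUSE_DEVELOPMENT_RATE = 0.8  # year^-2, Gaussian rise during development


class FastExchangeWarning(UserWarning):
    """Fusion/fission exchange not fast relative to the biogenesis/mitophagy
    imbalance; the single-exponential picture degrades."""


@dataclass(frozen=True)
class MitoParams:
    """Transition rates (per year) and turnover time of the mt system."""

    p11: float   # biogenesis rate
    p12: float   # fission -> fusion
    p21: float   # fusion -> fission
    p13: float   # mitophagy rate
    tot: float | None = None   # turnover time, years

    def __post_init__(self) -> None:
        for name in ("p11", "p12", "p21", "p13"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tot is not None and self.tot <= 0:
            raise ValueError("tot must be positive")
        imbalance = abs(self.p13 - self.p11)
        if imbalance > 0 and self.p12 + self.p21 < 10 * imbalance:
            warnings.warn(
                "P12 + P21 is not >> |P13 - P11|; the slow-mode "
                "approximation u ~ P21*(P13-P11)/(P12+P21) degrades",
                FastExchangeWarning, stacklevel=2)


def slow_decay_constant(params: MitoParams) -> float:
    """Exact slow root u = (B - sqrt(B^2 - 4C))/2 of the transport system."""
    b = params.p12 + params.p21 + params.p13 - params.p11
    c = params.p21 * (params.p13 - params.p11)
    disc = b * b - 4.0 * c
    if disc < 0:
        raise ValueError("complex characteristic roots: outside the "
                         "overdamped regime the model assumes")
    return (b - np.sqrt(disc)) / 2.0


def approx_decay_constant(params: MitoParams) -> float:
    """Fast-exchange approximation u ~ P21*(P13 - P11)/(P12 + P21)."""
    denom = params.p12 + params.p21
    if denom == 0:
        raise ValueError("P12 + P21 must be positive")
    return params.p21 * (params.p13 - params.p11) / denom


def analytic_solution(params: MitoParams, n2_0: float,
                      times) -> pd.DataFrame:
    """Slow-eigenmode solution of the transport equations.

    N2(T) = N2(0)*exp(-u*T) and N1(T) = N2(0)*(P21 - u)/P12*exp(-u*T) (the
    fission/fusion occupancy ratio of the slow mode), so the total decays as
    one exponential.  Returns a DataFrame ``t, n1, n2, n_total``.
    """
    if params.p12 == 0:
        raise ValueError("P12 must be positive for the two-state solution")
    t = np.asarray(times, dtype=float)
    u = slow_decay_constant(params)
    decay = np.exp(-u * t)
    n2 = n2_0 * decay
    n1 = n2_0 * (params.p21 - u) / params.p12 * decay
    return pd.DataFrame({"t": t, "n1": n1, "n2": n2, "n_total": n1 + n2})


def slow_mode_n1(params: MitoParams, n2_0: float) -> float:
    """N1 consistent with the slow eigenmode for a given N2."""
    return n2_0 * (params.p21 - slow_decay_constant(params)) / params.p12


def numeric_oracle(params: MitoParams, n1_0: float, n2_0: float,
                   times) -> pd.DataFrame:
    """High-accuracy initial-value integration of the transport equations.

    Independent of the analytic path: integrates the raw 2x2 linear system
    with DOP853 at rtol 1e-12.  Returns ``t, n1, n2, n_total``.
    """
    t = np.asarray(times, dtype=float)

    def rhs(_, y):
        n1, n2 = y
        return [-(params.p12 + params.p13 - params.p11) * n1
                + params.p21 * n2,
                -params.p21 * n2 + params.p12 * n1]

    sol = solve_ivp(rhs, (t[0], t[-1]), [n1_0, n2_0], t_eval=t,
                    method="DOP853", rtol=1e-12, atol=1e-12)
    if not sol.success:   # pragma: no cover - linear system always integrates
        raise RuntimeError(f"integration failed: {sol.message}")
    n1, n2 = sol.y
    return pd.DataFrame({"t": t, "n1": n1, "n2": n2, "n_total": n1 + n2})


def decay_constant(p11: float, p13: float, tot: float) -> float:
    """Decay constant from the turnover identity: u = (P13-P11)/(P11*TOT)."""
    if p11 <= 0 or tot <= 0:
        raise ValueError("P11 and TOT must be positive")
    return (p13 - p11) / (p11 * tot)


def project_decline(n0: float, u: float, years: float) -> float:
    """Mitochondrial count after ``years`` of exponential decay, N0*e^(-u*t).

    Returns the continuous value; round for display as a count.
    """
    if n0 < 0 or years < 0:
        raise ValueError("n0 and years must be non-negative")
    return n0 * np.exp(-u * years)


def mouse_rescale(age, u_organ: float = 0.00624,
                  lifespan_ratio: float = MOUSE_LIFESPAN_RATIO,
                  f0_mouse: float = MOUSE_F0,
                  t_offset: float = MOUSE_T_OFFSET):
    """Adult mouse mt-density decline from a human organ decay constant.

    The human decline is compressed onto the mouse lifespan:
    F(T) = f0_mouse * exp{-lifespan_ratio * u_organ * (T - t_offset)} for
    mouse age T >= t_offset (years).  Default u_organ is the liver value.
    """
    if u_organ <= 0 or lifespan_ratio <= 0 or f0_mouse <= 0:
        raise ValueError("u_organ, lifespan_ratio and f0_mouse must be > 0")
    age = np.asarray(age, dtype=float)
    if np.any(age < t_offset):
        raise ValueError(
            f"adult decline defined for T >= {t_offset} (development phase "
            "is covered by mouse_development_curve)")
    out = f0_mouse * np.exp(-lifespan_ratio * u_organ * (age - t_offset))
    return out if out.ndim else float(out)


def mouse_development_curve(age, f0_mouse: float = MOUSE_F0,
                            rate: float = MOUSE_DEVELOPMENT_RATE,
                            t_offset: float = MOUSE_T_OFFSET):
    """Gaussian rise of the mouse mt density during development.

    f0_mouse * exp{-rate*(T - t_offset)^2} for 0 <= T <= t_offset; meets the
    adult decline continuously at T = t_offset.
    """
    age = np.asarray(age, dtype=float)
    if np.any((age < 0) | (age > t_offset)):
        raise ValueError(f"development phase is 0 <= T <= {t_offset}")
    out = f0_mouse * np.exp(-rate * (age - t_offset) ** 2)
    return out if out.ndim else float(out)
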