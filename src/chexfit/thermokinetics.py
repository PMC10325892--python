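"""Kinetic and thermodynamic post-processing of fitted exchange parameters.

Converts the (kex, p_ES) pairs delivered by the CPMG/CEST fits into
forward/backward rates k_GE = kex p_ES and k_EG = kex (1 - p_ES), exchange
timescales, excited-state free energies, and -- across temperatures -- an
Arrhenius activation energy from ln k versus 1/T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_KCAL",
    "ArrheniusResult",
    "decompose_rates",
    "exchange_timescale",
    "arrhenius_fit",
    "arrhenius_rate",
    "state_free_energy",
]

# gas constant in kcal mol^-1 K^-1
R_KCAL = 1.98720425e-3


def decompose_rates(kex: float, p_es: float) -> tuple[float, float]:
    """Forward and backward rates (k_GE, k_EG) of the GS ⇌ ES equilibrium.

    k_GE = kex p_ES, k_EG = kex (1 - p_ES); the sum reproduces kex exactly.
    """
    if kex < 0:
        raise ValueError("kex must be non-negative")
    if not 0.0 <= p_es <= 1.0:
        raise ValueError("p_es must lie in [0, 1]")
    k_ge = kex * p_es
    return k_ge, kex - k_ge


def exchange_timescale(kex: float) -> float:
    """Exchange timescale tau_ex = 1/kex, in microseconds."""
    if kex <= 0:
        raise ValueError("kex must be positive")
    return 1e6 / kex


def arrhenius_rate(t_kelvin, ea_kcal: float, t_ref: float, k_ref: float):
    """Rate at temperature T from an Arrhenius law anchored at (t_ref, k_ref)."""
    t = np.asarray(t_kelvin, dtype=float)
    return k_ref * np.exp(-ea_kcal / R_KCAL * (1.0 / t - 1.0 / t_ref))


@dataclass
class ArrheniusResult:
    ea_kcal: float            # activation energy, kcal/mol
    ea_err: float
    ln_a: float               # pre-exponential (intercept of ln k vs 1/T)
    r_squared: float
    rates: list = field(default_factory=list)   # (T in K, k in 1/s) as used
    flags: list = field(default_factory=list)


def arrhenius_fit(rates: list[tuple[float, float]],
                  errors: list[float] | None = None) -> ArrheniusResult:
    """Activation energy from (weighted) linear regression of ln k on 1/T.

    Ea = -slope * R with R in kcal/(mol K).  With exactly two temperatures
    the line is exact and the error undefined (flagged).  ``errors`` are
    optional 1-sigma rate errors; weights default to equal because
    per-temperature rate uncertainties are often unavailable.
    """
    rates = [(float(t), float(k)) for t, k in rates]
    temps = np.array([t for t, _ in rates])
    ks = np.array([k for _, k in rates])
    if len(np.unique(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    if np.any(ks <= 0):
        raise ValueError("rates must be positive")
    x = 1.0 / temps
    y = np.log(ks)
    if errors is not None:
        w = (np.asarray(ks) / np.asarray(errors)) ** 2  # var(ln k) = (err/k)^2
    else:
        w = np.ones_like(y)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    yhat = slope * x + intercept
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    flags = []
    if len(rates) <= 2:
        slope_err = np.nan
        flags.append("two points: exact line, error undefined")
    else:
        s2 = ss_res / (len(rates) - 2)
        slope_err = float(np.sqrt(s2 / sxx))
    return ArrheniusResult(
        ea_kcal=-slope * R_KCAL,
        ea_err=(abs(slope_err) * R_KCAL if np.isfinite(slope_err) else np.nan),
        ln_a=intercept,
        r_squared=r2,
        rates=rates,
        flags=flags)


def state_free_energy(p_es: float, t_kelvin: float) -> float:
    """Free-energy difference GS -> ES, dG = -RT ln(p_ES/(1-p_ES)), kcal/mol."""
    if not 0.0 < p_es < 1.0:
        raise ValueError("p_es must lie strictly between 0 and 1")
    return -R_KCAL * t_kelvin * np.log(p_es / (1.0 - p_es))
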