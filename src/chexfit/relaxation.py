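"""Per-residue spin-relaxation fits: R1/R2 exponential decays and hetNOE ratios.

Longitudinal (R1) and transverse (R2) rates are obtained from two-parameter
exponential fits I(t) = A exp(-R t); constant offsets are assumed subtracted
upstream, which keeps the model identifiable with the 6-8 delay points these
experiments typically use.  The steady-state heteronuclear NOE is the plain
intensity ratio with/without proton saturation, with first-order error
propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datamodel import RelaxationSeries, ResidueID

__all__ = ["RateResult", "fit_exponential", "het_noe", "InsufficientDataError"]


class InsufficientDataError(ValueError):
    pass


@dataclass
class RateResult:
    residue: ResidueID
    rate: float           # s^-1
    amplitude: float
    rate_err: float       # 1 sigma
    amplitude_err: float
    residual_norm: float
    converged: bool = True
    message: str = ""


def _decay(t, a, r):
    return a * np.exp(-r * t)


def fit_exponential(series: RelaxationSeries) -> RateResult:
    """Least-squares fit of a mono-exponential decay to one relaxation series.

    Parameter errors come from the fit covariance scaled by the reduced
    chi-square (per-point intensity errors are typically unavailable for
    these experiments).  A rate pinned at zero is flagged as non-converged.
    """
    t = series.delays
    y = series.intensities
    if len(np.unique(t)) < 3:
        raise InsufficientDataError(
            f"{series.residue}: need >= 3 distinct delays, got {len(np.unique(t))}")

    # normalize so the fit (and its convergence tolerances) are exactly
    # scale-free; the amplitude is rescaled afterwards
    y_scale = float(np.max(np.abs(y))) or 1.0
    y = y / y_scale
    a0 = 1.0
    # crude rate guess from the log-ratio of first and last positive points
    pos = y > 0
    if pos.sum() >= 2:
        t0, t1 = t[pos][0], t[pos][-1]
        y0, y1 = y[pos][0], y[pos][-1]
        r0 = abs(np.log(y0 / y1) / (t1 - t0)) if t1 > t0 and y1 != y0 else 1.0 / t.max()
    else:
        r0 = 1.0 / t.max()
    r0 = float(np.clip(r0, 1e-6, 1e4))

    try:
        popt, pcov = curve_fit(
            _decay, t, y, p0=[a0, r0],
            bounds=([-np.inf, 0.0], [np.inf, np.inf]),
            xtol=1e-13, ftol=1e-13, gtol=1e-13, maxfev=10000)
    except RuntimeError as exc:
        return RateResult(series.residue, np.nan, np.nan, np.nan, np.nan,
                          np.nan, converged=False, message=str(exc))
    resid = (y - _decay(t, *popt)) * y_scale
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    # covariance already reflects unit weights; scale to the observed scatter
    # a decay of < 0.1% over the sampled window is indistinguishable from a
    # constant series: flag rather than report a boundary rate
    converged = popt[1] * t.max() > 1e-3 and np.isfinite(perr).all()
    return RateResult(
        residue=series.residue,
        rate=float(popt[1]),
        amplitude=float(popt[0] * y_scale),
        rate_err=float(perr[1]),
        amplitude_err=float(perr[0] * y_scale),
        residual_norm=float(np.sqrt(resid @ resid)),
        converged=bool(converged),
        message="" if converged else "rate at zero boundary or undefined errors",
    )


def het_noe(saturated: RelaxationSeries, reference: RelaxationSeries
            ) -> tuple[float, float]:
    """Heteronuclear NOE ratio I_sat/I_ref with propagated 1-sigma error.

    Negative ratios are passed through (flexible termini give negative NOEs).
    """
    if saturated.residue != reference.residue:
        raise ValueError("saturated and reference series are for different residues")
    if len(saturated.intensities) != 1 or len(reference.intensities) != 1:
        raise ValueError("hetNOE series must carry exactly one intensity each")
    i_sat = float(saturated.intensities[0])
    i_ref = float(reference.intensities[0])
    if i_ref == 0.0:
        raise ZeroDivisionError(f"{reference.residue}: reference intensity is zero")
    s_sat = float(saturated.errors[0])
    s_ref = float(reference.errors[0])
    ratio = i_sat / i_ref
    err = np.sqrt((s_sat / i_ref) ** 2 + (i_sat * s_ref / i_ref**2) ** 2)
    return ratio, float(err)
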